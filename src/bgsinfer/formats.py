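"""File formats: BED, VCF, SFS dialects, multihetsep, rate maps, tables.

Everything internal is 0-based half-open; 1-based conventions (VCF,
multihetsep) are converted at the boundary of this module only.

SFS file dialect: a header line ``#n_hap=<k> folded=<0|1>`` followed by
one whitespace-separated line of n_hap+1 integer counts (monomorphic
class first). The fastsimcoal-style ``_DAFpop0.obs`` dialect is::

    1 observations
    d0_0<TAB>d0_1<TAB>...<TAB>d0_<n>
    c0<TAB>c1<TAB>...<TAB>c<n>
"""

from __future__ import annotations

import io as _io
from typing import Iterable, TextIO

import numpy as np

from .masks import MaskSet
from .ratemaps import RateMaps, StepMap
from .samples import HaplotypeSample
from .sumstats import SFS, STAT_FIELDS, WindowStats

__all__ = [
    "write_bed",
    "write_layout_bed",
    "write_vcf",
    "read_vcf",
    "write_sfs",
    "read_sfs",
    "write_dafpop0",
    "write_multihetsep",
    "read_recombination_map",
    "read_mutation_map",
    "read_rate_maps",
    "write_stats_table",
    "write_reference_table",
    "read_reference_table",
]


def _as_handle(f, mode="w"):
    if isinstance(f, (str, bytes)) or hasattr(f, "__fspath__"):
        return open(f, mode), True
    return f, False


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple[int, int]], f, chrom_name: str = "chr1",
              label: str | None = None) -> None:
    fh, close = _as_handle(f)
    try:
        for s, e in intervals:
            row = f"{chrom_name}\t{s}\t{e}"
            if label:
                row += f"\t{label}"
            fh.write(row + "\n")
    finally:
        if close:
            fh.close()


def write_layout_bed(layout, prefix: str, chrom_name: str = "chr1") -> None:
    """Emit <prefix>.{exons,introns,intergenic,genes}.bed."""
    for kind in ("exon", "intron", "intergenic", "gene"):
        ivs = getattr(layout, f"{kind}_intervals")
        write_bed(ivs, f"{prefix}.{kind}s.bed", chrom_name=chrom_name, label=kind)


# ---------------------------------------------------------------------------
# VCF (phased diploid)
# ---------------------------------------------------------------------------

def write_vcf(sample: HaplotypeSample, f, contig_prefix: str = "chr",
              config_hash: str | None = None) -> None:
    """Minimal phased-diploid VCF; REF=ancestral (A), ALT=derived (T)."""
    fh, close = _as_handle(f)
    try:
        fh.write("##fileformat=VCFv4.2\n")
        if config_hash:
            fh.write(f"##bgsinfer_config_hash={config_hash}\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in enumerate(sample.chrom_lengths):
            fh.write(f"##contig=<ID={contig_prefix}{c + 1},length={ln}>\n")
        names = "\t".join(f"ind{i}" for i in range(sample.n_diploids))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        H = sample.haplotypes
        for j in range(sample.n_sites):
            gts = "\t".join(
                f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(sample.n_diploids)
            )
            fh.write(
                f"{contig_prefix}{sample.chrom[j] + 1}\t{sample.positions[j] + 1}\t.\t"
                f"A\tT\t.\tPASS\tAA=A\tGT\t{gts}\n"
            )
    finally:
        if close:
            fh.close()


def read_vcf(f) -> HaplotypeSample:
    """Read a VCF produced by :func:`write_vcf` back into a sample."""
    fh, close = _as_handle(f, "r")
    try:
        contigs: dict[str, int] = {}
        lengths: list[int] = []
        rows: list[tuple[int, int, list[int]]] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##contig"):
                inner = line[line.index("<") + 1 : line.rindex(">")]
                kv = dict(p.split("=", 1) for p in inner.split(","))
                contigs[kv["ID"]] = len(lengths)
                lengths.append(int(kv["length"]))
            elif line.startswith("#"):
                continue
            else:
                parts = line.split("\t")
                alleles = []
                for gt in parts[9:]:
                    a, b = gt.split("|")
                    alleles += [int(a), int(b)]
                rows.append((contigs[parts[0]], int(parts[1]) - 1, alleles))
        if rows:
            hap = np.array([r[2] for r in rows], dtype=np.uint8).T
            chrom = np.array([r[0] for r in rows], dtype=np.int32)
            pos = np.array([r[1] for r in rows], dtype=np.int64)
        else:
            hap = np.empty((0, 0), np.uint8)
            chrom = np.empty(0, np.int32)
            pos = np.empty(0, np.int64)
        return HaplotypeSample(
            haplotypes=hap,
            positions=pos,
            chrom=chrom,
            chrom_lengths=tuple(lengths),
            n_diploids=hap.shape[0] // 2 if hap.size else len(rows[0][2]) // 2 if rows else 0,
        )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# SFS dialects
# ---------------------------------------------------------------------------

def write_sfs(sfs: SFS, f, config_hash: str | None = None) -> None:
    fh, close = _as_handle(f)
    try:
        fh.write(f"#n_hap={sfs.n_hap} folded={int(sfs.folded)}"
                 + (f" config={config_hash}" if config_hash else "") + "\n")
        fh.write(" ".join(str(int(c)) for c in sfs.counts) + "\n")
    finally:
        if close:
            fh.close()


def read_sfs(f) -> SFS:
    fh, close = _as_handle(f, "r")
    try:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing SFS header line")
        kv = dict(p.split("=") for p in header[1:].split())
        counts = np.array(fh.readline().split(), dtype=np.int64)
        return SFS(counts=counts, n_hap=int(kv["n_hap"]), folded=bool(int(kv["folded"])))
    finally:
        if close:
            fh.close()


def write_dafpop0(sfs: SFS, f) -> None:
    """fastsimcoal-style derived-allele-frequency observation file."""
    if sfs.folded:
        raise ValueError("DAF file requires the unfolded SFS")
    fh, close = _as_handle(f)
    try:
        fh.write("1 observations\n")
        fh.write("\t".join(f"d0_{b}" for b in range(sfs.n_hap + 1)) + "\n")
        fh.write("\t".join(str(int(c)) for c in sfs.counts) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# multihetsep (MSMC input)
# ---------------------------------------------------------------------------

def write_multihetsep(
    sample: HaplotypeSample, mask: MaskSet | None = None, f=None
) -> str | None:
    """MSMC multihetsep export: chrom, 1-based pos, called sites, genotypes.

    The third column counts callable (unmasked) sites since the previous
    emitted segregating site, inclusive of the current one; segregating
    sites inside masked intervals are dropped. Alleles are written as
    'A' (ancestral) / 'C' (derived), phased, one character per haplotype.
    Returns the text when ``f`` is None.
    """
    out = _io.StringIO() if f is None else f
    fh, close = _as_handle(out) if f is not None else (out, False)
    try:
        for c, ln in enumerate(sample.chrom_lengths):
            sel = np.flatnonzero(sample.chrom == c)
            pos = sample.positions[sel]
            if mask is not None and pos.size:
                masked = mask.is_masked(c, pos)
                sel, pos = sel[~masked], pos[~masked]
            prev = -1  # previous segregating position (0-based)
            for idx, p in zip(sel, pos):
                called = p - prev
                if mask is not None:
                    ivs = mask.intervals.get(c, ())
                    for s, e in ivs:
                        lo, hi = max(s, prev + 1), min(e, p + 1)
                        if hi > lo:
                            called -= hi - lo
                prev = p
                if called <= 0:
                    continue
                gt = "".join("C" if a else "A" for a in sample.haplotypes[:, idx])
                fh.write(f"{c + 1}\t{p + 1}\t{called}\t{gt}\n")
        return out.getvalue() if f is None else None
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Rate maps
# ---------------------------------------------------------------------------

def read_recombination_map(f, chrom_length: float | None = None) -> StepMap:
    """HapMap-style text map: columns position(bp) and rate(cM/Mb).

    The rate on each line applies from that position to the next; the
    region before the first position inherits the first rate, the region
    after the last position the last rate. 1 cM/Mb = 1e-8 crossovers per
    bp per generation.
    """
    fh, close = _as_handle(f, "r")
    try:
        pos, rates = [], []
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith(("position", "pos", "chr", "#")):
                continue
            parts = line.split()
            if len(parts) >= 3 and not parts[0].replace(".", "").isdigit():
                parts = parts[1:]  # leading chromosome column
            pos.append(float(parts[0]))
            rates.append(float(parts[1]) * 1e-8)
        if not pos:
            raise ValueError("empty recombination map")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("map positions must be strictly increasing")
        end = chrom_length if chrom_length is not None else pos[-1] + (pos[-1] - pos[0])
        breaks = np.asarray([0.0] + pos + [float(end)])
        vals = np.asarray([rates[0]] + rates)
        keep = np.diff(breaks) > 0  # collapse zero-width leading/trailing windows
        return StepMap(np.concatenate([[breaks[0]], breaks[1:][keep]]), vals[keep])
    finally:
        if close:
            fh.close()


def read_mutation_map(f, chrom_length: float | None = None) -> StepMap:
    """Two-column window file: window start (bp) and per-site mutation rate.

    Windows with missing data (gaps larger than the modal window size, or
    negative rates) inherit the previous window's rate.
    """
    fh, close = _as_handle(f, "r")
    try:
        starts, rates = [], []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            starts.append(float(a))
            rates.append(float(b))
        if not starts:
            raise ValueError("empty mutation map")
        if any(y <= x for x, y in zip(starts, starts[1:])):
            raise ValueError("windows must be sorted and non-overlapping")
        widths = np.diff(starts)
        wsize = float(np.min(widths)) if widths.size else 1.0
        breaks = [0.0]
        vals: list[float] = []
        prev_rate = max(rates[0], 0.0)
        for st, r in zip(starts, rates):
            if st > breaks[-1]:
                breaks.append(st)
                vals.append(prev_rate)  # gap: previous window's rate
            rate = r if r >= 0 else prev_rate
            breaks.append(st + wsize)
            vals.append(rate)
            prev_rate = rate
        end = chrom_length if chrom_length is not None else breaks[-1]
        if end > breaks[-1]:
            breaks.append(float(end))
            vals.append(prev_rate)
        # drop zero-width leading interval if first window starts at 0
        b = np.asarray(breaks)
        v = np.asarray(vals)
        keep = np.diff(b) > 0
        return StepMap(np.concatenate([[b[0]], b[1:][keep]]), v[keep])
    finally:
        if close:
            fh.close()


def read_rate_maps(
    rec_map_file,
    mut_map_file,
    target_mean_mu: float = 1e-8,
    chrom_length: float | None = None,
    centromere: tuple[float, float] | None = None,
) -> RateMaps:
    """Read both maps, normalize the mutation map's mean, zero centromeric rec."""
    rec = read_recombination_map(rec_map_file, chrom_length)
    mut = read_mutation_map(mut_map_file, chrom_length or rec.length)
    if abs(rec.length - mut.length) > 0.5:
        L = max(rec.length, mut.length)
        rec = _extend(rec, L)
        mut = _extend(mut, L)
    if centromere is not None:
        s, e = centromere
        rec = _set_zero(rec, s, e)
    return RateMaps(recombination=rec, mutation=mut).normalized(target_mean_mu)


def _extend(m: StepMap, L: float) -> StepMap:
    if m.length >= L:
        return m
    return StepMap(np.append(m.breaks, L), np.append(m.rates, m.rates[-1]))


def _set_zero(m: StepMap, s: float, e: float) -> StepMap:
    breaks = np.unique(np.concatenate([m.breaks, [s, e]]))
    mids = 0.5 * (breaks[1:] + breaks[:-1])
    rates = m.rate_at(mids)
    rates[(mids >= s) & (mids < e)] = 0.0
    return StepMap(breaks, rates)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_stats_table(stats: list[WindowStats], f) -> None:
    """TSV of per-window statistics in the fixed column order."""
    fh, close = _as_handle(f)
    try:
        cols = ("chrom", "start", "end", "n_snps") + STAT_FIELDS
        fh.write("\t".join(cols) + "\n")
        for w in stats:
            fh.write("\t".join(repr(getattr(w, c)) for c in cols) + "\n")
    finally:
        if close:
            fh.close()


def write_reference_table(table, prefix: str) -> None:
    """ABC reference table as TSV plus a JSON provenance sidecar."""
    import json

    from .abc_infer import ReferenceTable  # noqa: F401 (type)
    from .sumstats import STAT_FIELDS as SF

    header = ["Nanc", "Ncur", "f0", "f1", "f2", "f3"] + [
        f"mean_{s}" for s in SF
    ] + [f"var_{s}" for s in SF]
    data = np.hstack([table.params, table.stats])
    with open(f"{prefix}.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in data:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {
                "engine": "forward-wright-fisher",
                "mode": table.mode,
                "seed": table.seed,
                "config_hash": table.config_hash,
                "n_rows": table.n_rows,
                "n_failed": table.n_failed,
            },
            fh,
            indent=2,
        )


def read_reference_table(prefix: str):
    import json

    from .abc_infer import ReferenceTable

    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    data = np.loadtxt(f"{prefix}.tsv", skiprows=1)
    data = np.atleast_2d(data)
    return ReferenceTable(
        params=data[:, :6],
        stats=data[:, 6:],
        config_hash=meta["config_hash"],
        mode=meta["mode"],
        seed=meta["seed"],
        n_failed=meta.get("n_failed", 0),
    )
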