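"""Rule-based calling of putative direct transcription-factor targets.

A differentially expressed (DE) gene is called a putative direct target
when a binding peak lies

* within ``tss_bp`` (default 1000 bp) of its transcription start site, or
* inside one of its introns (>= 1 bp overlap), or
* within ``loop_bp`` (default 500 bp) of a chromatin loop one of whose
  anchors maps to the gene's TSS (anchor within ``loop_tss_bp`` of the
  TSS; default equals ``tss_bp``).

All coordinates are 0-based half-open. Distances are gap distances: zero
for any overlap, otherwise the minimal boundary gap. Features on
different chromosomes are infinitely distant (never an error).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

Interval = Tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """Gene identifier, strand-aware TSS position, and intron intervals."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    introns: Tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS coordinate")
        introns = tuple(sorted((int(a), int(b)) for a, b in self.introns))
        for a, b in introns:
            if b <= a:
                raise ValueError(f"{self.gene_id}: intron end <= start ({a}, {b})")
            if a < 0:
                raise ValueError(f"{self.gene_id}: negative intron coordinate")
        for (a1, b1), (a2, b2) in zip(introns, introns[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: overlapping introns")
        object.__setattr__(self, "introns", introns)


@dataclass(frozen=True)
class Peak:
    """A binding peak as a half-open interval [start, end)."""

    peak_id: str
    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.peak_id}: end <= start")
        if self.start < 0:
            raise ValueError(f"{self.peak_id}: negative coordinate")


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two half-open anchor intervals."""

    loop_id: str
    chrom_a: str
    anchor_a: Interval
    chrom_b: str
    anchor_b: Interval

    def __post_init__(self) -> None:
        for name, (a, b) in (("anchor_a", self.anchor_a), ("anchor_b", self.anchor_b)):
            if b <= a:
                raise ValueError(f"{self.loop_id}: degenerate {name}")
            if a < 0:
                raise ValueError(f"{self.loop_id}: negative coordinate in {name}")

    @property
    def intra_chromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b


@dataclass
class TargetCall:
    """Classification of one DE gene with its supporting evidence.

    ``evidence`` maps category -> list of dicts naming the peak (and loop)
    ids and gap distances in bp that back the call.
    """

    gene_id: str
    is_target: bool
    categories: Set[str] = field(default_factory=set)
    evidence: Dict[str, List[dict]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_target != bool(self.categories):
            raise ValueError("is_target must match categories being non-empty")
        for cat in self.categories:
            if not self.evidence.get(cat):
                raise ValueError(f"category {cat!r} lacks supporting evidence")


@dataclass(frozen=True)
class TargetParams:
    """Distance thresholds of the calling rule (bp)."""

    tss_bp: int = 1000
    loop_bp: int = 500
    loop_tss_bp: Optional[int] = None  # defaults to tss_bp
    other_anchor_only: bool = False  # stricter mode: peak near the non-TSS anchor

    @property
    def resolved_loop_tss_bp(self) -> int:
        return self.tss_bp if self.loop_tss_bp is None else self.loop_tss_bp


def interval_gap(a: Interval, b: Interval) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap or touch."""
    return max(a[0] - b[1], b[0] - a[1], 0)


def point_gap(point: int, interval: Interval) -> int:
    """Gap in bp from a position to a half-open interval (0 if covered)."""
    return max(interval[0] - point, point - interval[1], 0)


def distance(
    a: Interval | int,
    b: Interval | int,
    chrom_a: Optional[str] = None,
    chrom_b: Optional[str] = None,
) -> float:
    """Gap distance between points and/or intervals; +inf across chromosomes.

    Symmetric; 0 whenever the features overlap or one contains the other.
    """
    if chrom_a is not None and chrom_b is not None and chrom_a != chrom_b:
        return math.inf
    a_iv = (a, a) if isinstance(a, int) else (int(a[0]), int(a[1]))
    b_iv = (b, b) if isinstance(b, int) else (int(b[0]), int(b[1]))
    return float(max(a_iv[0] - b_iv[1], b_iv[0] - a_iv[1], 0))


def _peak_trees(peaks: Sequence[Peak]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def _anchor_trees(loops: Sequence[Loop]) -> Dict[str, IntervalTree]:
    """Index both anchors of every intra-chromosomal loop."""
    trees: Dict[str, IntervalTree] = {}
    for lp in loops:
        if not lp.intra_chromosomal:
            continue
        for which, (a, b) in (("a", lp.anchor_a), ("b", lp.anchor_b)):
            trees.setdefault(lp.chrom_a, IntervalTree()).addi(a, b, (lp, which))
    return trees


def _peaks_near(
    tree: Optional[IntervalTree], lo: int, hi: int
) -> List[Peak]:
    """Peaks overlapping the half-open query window [lo, hi)."""
    if tree is None:
        return []
    return sorted((iv.data for iv in tree.overlap(max(lo, 0), max(hi, 1))),
                  key=lambda p: p.peak_id)


def call_targets(
    genes: Sequence[GeneModel],
    peaks: Sequence[Peak],
    loops: Sequence[Loop],
    de_list: Iterable[str],
    params: TargetParams = TargetParams(),
) -> List[TargetCall]:
    """Classify each DE gene as tss / intron / loop target or non-target.

    DE identifiers absent from ``genes`` are skipped (callers can compare
    the returned gene ids against the DE list to report them). Output order
    follows the sorted DE list and is independent of the input ordering of
    peaks, loops and genes.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    peak_trees = _peak_trees(peaks)
    anchor_trees = _anchor_trees(loops)
    tss_bp = params.tss_bp
    loop_bp = params.loop_bp
    loop_tss_bp = params.resolved_loop_tss_bp

    calls: List[TargetCall] = []
    for gid in sorted(set(de_list)):
        gene = gene_by_id.get(gid)
        if gene is None:
            continue
        ptree = peak_trees.get(gene.chrom)
        categories: Set[str] = set()
        evidence: Dict[str, List[dict]] = {}

        # TSS rule: any peak whose gap to the TSS point is <= tss_bp.
        tss_hits = []
        for p in _peaks_near(ptree, gene.tss - tss_bp - 1, gene.tss + tss_bp + 1):
            d = point_gap(gene.tss, (p.start, p.end))
            if d <= tss_bp:
                tss_hits.append({"peak_id": p.peak_id, "distance_bp": d})
        if tss_hits:
            categories.add("tss")
            evidence["tss"] = tss_hits

        # Intron rule: >= 1 bp overlap with any intron.
        intron_hits = []
        seen = set()
        for intron in gene.introns:
            for p in _peaks_near(ptree, intron[0], intron[1]):
                key = (p.peak_id, intron)
                if key in seen:
                    continue
                seen.add(key)
                intron_hits.append(
                    {"peak_id": p.peak_id, "intron": list(intron), "distance_bp": 0}
                )
        if intron_hits:
            categories.add("intron")
            evidence["intron"] = intron_hits

        # Loop rule: a loop anchor maps to the TSS and a peak sits within
        # loop_bp of the loop's anchor(s).
        loop_hits = []
        atree = anchor_trees.get(gene.chrom)
        seen_loops = set()
        if atree is not None:
            near = atree.overlap(max(gene.tss - loop_tss_bp - 1, 0),
                                 gene.tss + loop_tss_bp + 1)
            for iv in sorted(near, key=lambda iv: iv.data[0].loop_id):
                lp, which = iv.data
                anchor = lp.anchor_a if which == "a" else lp.anchor_b
                if point_gap(gene.tss, anchor) > loop_tss_bp:
                    continue
                if lp.loop_id in seen_loops:
                    continue
                other = lp.anchor_b if which == "a" else lp.anchor_a
                search = [other] if params.other_anchor_only else [lp.anchor_a, lp.anchor_b]
                hits_for_loop = []
                for anc in search:
                    for p in _peaks_near(ptree, anc[0] - loop_bp - 1, anc[1] + loop_bp + 1):
                        d = interval_gap((p.start, p.end), anc)
                        if d <= loop_bp:
                            hits_for_loop.append(
                                {"peak_id": p.peak_id, "loop_id": lp.loop_id,
                                 "distance_bp": d}
                            )
                if hits_for_loop:
                    seen_loops.add(lp.loop_id)
                    loop_hits.extend(hits_for_loop)
        if loop_hits:
            categories.add("loop")
            evidence["loop"] = loop_hits

        calls.append(
            TargetCall(gene_id=gid, is_target=bool(categories),
                       categories=categories, evidence=evidence)
        )
    return calls


def calls_to_frame(calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Tidy TSV-ready table of target calls."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "is_target": c.is_target,
                "categories": ",".join(sorted(c.categories)) or "none",
                "n_tss_peaks": len(c.evidence.get("tss", [])),
                "n_intron_peaks": len(c.evidence.get("intron", [])),
                "n_loop_peaks": len(c.evidence.get("loop", [])),
                "min_tss_distance_bp": min(
                    (e["distance_bp"] for e in c.evidence.get("tss", [])), default=""
                ),
            }
        )
    return pd.DataFrame(rows)


def summarize_calls(calls: Sequence[TargetCall]) -> Dict[str, int]:
    summary = {
        "n_genes": len(calls),
        "n_targets": sum(c.is_target for c in calls),
        "tss": sum("tss" in c.categories for c in calls),
        "intron": sum("intron" in c.categories for c in calls),
        "loop": sum("loop" in c.categories for c in calls),
        "none": sum(not c.is_target for c in calls),
    }
    return summary


# --------------------------------------------------------------------------
# Readers (plain-text genomic formats; errors carry line numbers)
# --------------------------------------------------------------------------

class GenomicFormatError(ValueError):
    pass


def read_bed(path: str | Path) -> List[Peak]:
    """Read peaks from BED3+ (0-based half-open, as BED is natively)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomicFormatError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise GenomicFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak{lineno}"
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise GenomicFormatError(f"{path}:{lineno}: non-numeric score") from None
            try:
                peaks.append(Peak(peak_id=name, chrom=fields[0], start=start,
                                  end=end, score=score))
            except ValueError as exc:
                raise GenomicFormatError(f"{path}:{lineno}: {exc}") from None
    return peaks


def read_bedpe(path: str | Path) -> List[Loop]:
    """Read chromatin loops from BEDPE (two half-open anchors per line)."""
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GenomicFormatError(f"{path}:{lineno}: expected >= 6 BEDPE fields")
            try:
                a = (int(fields[1]), int(fields[2]))
                b = (int(fields[4]), int(fields[5]))
            except ValueError:
                raise GenomicFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            name = fields[6] if len(fields) > 6 and fields[6] not in ("", ".") else f"loop{lineno}"
            try:
                loops.append(Loop(loop_id=name, chrom_a=fields[0], anchor_a=a,
                                  chrom_b=fields[3], anchor_b=b))
            except ValueError as exc:
                raise GenomicFormatError(f"{path}:{lineno}: {exc}") from None
    return loops


def read_genes_tsv(path: str | Path) -> List[GeneModel]:
    """Read gene models from the package's documented TSV.

    Columns: gene_id, chrom, strand, tss, introns — introns as
    semicolon-separated half-open ``start-end`` pairs (may be empty).
    """
    genes = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "chrom", "strand", "tss", "introns"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise GenomicFormatError(
                f"{path}: gene TSV must have columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            introns: List[Interval] = []
            raw = (row["introns"] or "").strip()
            if raw:
                for part in raw.split(";"):
                    try:
                        a, b = part.split("-")
                        introns.append((int(a), int(b)))
                    except ValueError:
                        raise GenomicFormatError(
                            f"{path}:{lineno}: malformed intron {part!r}"
                        ) from None
            try:
                genes.append(
                    GeneModel(gene_id=row["gene_id"], chrom=row["chrom"],
                              strand=row["strand"], tss=int(row["tss"]),
                              introns=tuple(introns))
                )
            except ValueError as exc:
                raise GenomicFormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_genes_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "chrom", "strand", "tss", "introns"])
        for g in genes:
            w.writerow([
                g.gene_id, g.chrom, g.strand, g.tss,
                ";".join(f"{a}-{b}" for a, b in g.introns),
            ])


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for p in peaks:
            w.writerow([p.chrom, p.start, p.end, p.peak_id,
                        "." if p.score is None else p.score])


def write_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for lp in loops:
            w.writerow([lp.chrom_a, lp.anchor_a[0], lp.anchor_a[1],
                        lp.chrom_b, lp.anchor_b[0], lp.anchor_b[1], lp.loop_id])


def read_de_list(path: str | Path, column: str = "gene_id") -> List[str]:
    """Read DE gene ids from a TSV (first column or a named column)."""
    df = pd.read_csv(path, sep="\t")
    col = column if column in df.columns else df.columns[0]
    return [str(v) for v in df[col].tolist()]


def read_ortholog_map(path: str | Path) -> Dict[str, str]:
    """Two-column TSV mapping source gene ids to annotation gene ids."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise GenomicFormatError(f"{path}: ortholog map needs two columns")
    return {str(a): str(b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_genes_gff3(path: str | Path) -> List[GeneModel]:
    """Read gene models from GFF3 via gffutils (1-based inclusive converted
    to 0-based half-open at this boundary). Introns are inferred as the
    gaps between consecutive exons of each gene's first mRNA."""
    try:
        import gffutils
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading GFF3 requires the optional gffutils dependency") from exc
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        strand = g.strand if g.strand in {"+", "-"} else "+"
        tss = g.start - 1 if strand == "+" else g.end - 1
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(g, featuretype="exon")),
        )
        introns = [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(exons, exons[1:])
            if b_start > a_end
        ]
        genes.append(GeneModel(gene_id=g.id, chrom=g.seqid, strand=strand,
                               tss=tss, introns=tuple(introns)))
    return genes
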