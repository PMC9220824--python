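"""Independent reference implementations used to cross-check the package.

These deliberately avoid the data structures of the library under test:
the target-calling oracle is a quadratic scan over every (gene, feature)
pair using plain gap arithmetic, and the duty-cycle oracle is direct
elevated-frame counting on rectangular traces.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def brute_force_targets(
    genes,
    peaks,
    loops,
    de_list: Sequence[str],
    tss_bp: int = 1000,
    loop_bp: int = 500,
    loop_tss_bp: int | None = None,
) -> Dict[str, Set[str]]:
    """Quadratic scan: for every DE gene, test every peak and loop directly.

    Returns {gene_id: set of categories} for DE ids present in ``genes``.
    Distances are gap distances on 0-based half-open intervals, matching
    the documented rule; everything is evaluated with vectorised numpy
    arithmetic, no interval index.
    """
    if loop_tss_bp is None:
        loop_tss_bp = tss_bp
    gene_by_id = {g.gene_id: g for g in genes}

    p_chrom = np.array([p.chrom for p in peaks])
    p_start = np.array([p.start for p in peaks], dtype=np.int64)
    p_end = np.array([p.end for p in peaks], dtype=np.int64)

    l_chrom_a = np.array([lp.chrom_a for lp in loops])
    l_chrom_b = np.array([lp.chrom_b for lp in loops])
    l_a0 = np.array([lp.anchor_a[0] for lp in loops], dtype=np.int64)
    l_a1 = np.array([lp.anchor_a[1] for lp in loops], dtype=np.int64)
    l_b0 = np.array([lp.anchor_b[0] for lp in loops], dtype=np.int64)
    l_b1 = np.array([lp.anchor_b[1] for lp in loops], dtype=np.int64)

    def point_to_iv_gap(point: int, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return np.maximum(np.maximum(lo - point, point - hi), 0)

    def iv_to_iv_gap(a0, a1, b0, b1) -> np.ndarray:
        return np.maximum(np.maximum(a0 - b1, b0 - a1), 0)

    out: Dict[str, Set[str]] = {}
    for gid in sorted(set(de_list)):
        gene = gene_by_id.get(gid)
        if gene is None:
            continue
        cats: Set[str] = set()
        same = p_chrom == gene.chrom

        if same.any():
            d_tss = point_to_iv_gap(gene.tss, p_start, p_end)
            if bool(np.any(same & (d_tss <= tss_bp))):
                cats.add("tss")
            for a, b in gene.introns:
                overlap = (p_start < b) & (p_end > a)
                if bool(np.any(same & overlap)):
                    cats.add("intron")
                    break

        if len(loops):
            intra = l_chrom_a == l_chrom_b
            on_chrom = intra & (l_chrom_a == gene.chrom)
            near_a = point_to_iv_gap(gene.tss, l_a0, l_a1) <= loop_tss_bp
            near_b = point_to_iv_gap(gene.tss, l_b0, l_b1) <= loop_tss_bp
            candidate = on_chrom & (near_a | near_b)
            for i in np.flatnonzero(candidate):
                if same.any():
                    ga = iv_to_iv_gap(p_start, p_end, l_a0[i], l_a1[i])
                    gb = iv_to_iv_gap(p_start, p_end, l_b0[i], l_b1[i])
                    hit = same & ((ga <= loop_bp) | (gb <= loop_bp))
                    if bool(np.any(hit)):
                        cats.add("loop")
                        break
        out[gid] = cats
    return out


def frame_count_duty(
    time: np.ndarray, values: np.ndarray, threshold: float
) -> Tuple[float, int]:
    """Elevated-frame-counting duty cycle for a rectangular trace.

    Cycles run from one rising edge to the next; the stretch before the
    first observed rising edge is discarded (its onset is unseen) and the
    last cycle closes at the window end. Returns (duty, n_cycles).
    """
    above = np.asarray(values) >= threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        # the leading elevated stretch has no observed onset
        pass
    if len(rising) == 0:
        return 0.0, 0
    start = rising[0]
    n_frames = len(above) - start
    n_elevated = int(above[start:].sum())
    return n_elevated / n_frames, len(rising)
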