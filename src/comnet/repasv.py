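"""Representative-taxon selection by abundance-occupancy sweep.

Microbial communities often lack a stable "core" at the finest unit, yet
a subset of abundant and prevalent taxa can reproduce the whole
community's beta diversity. Candidates are ranked by mean relative
abundance and by occupancy (fraction of samples where detected); for
each cutoff pair (top i% abundance AND top j% occupancy) the subset
table's ordination is superimposed on the full table's ordination by
Procrustes analysis, and the residual M² measures distortion. The
selected cutoffs are the elbow of the M²-versus-subset-size path: the
point with the steepest decrease in M² per added taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _scipy_procrustes

from .core_io import AbundanceTable, CountTable, relative_abundance
from .diversity import OrdinationResult, bray_curtis, pcoa, rarefy

logger = logging.getLogger(__name__)

__all__ = ["RepSelection", "summarize_taxa", "procrustes_m2", "sweep_select"]


@dataclass
class RepSelection:
    """Chosen (i%, j%) cutoffs, selected taxa, and their Procrustes M²."""

    i_pct: int
    j_pct: int
    subset: list[str]
    m2: float
    grid: pd.DataFrame | None = None  # columns: i, j, size, m2


def summarize_taxa(ra: AbundanceTable, count: CountTable) -> pd.DataFrame:
    """Per-taxon mean relative abundance and occupancy.

    Occupancy (prevalence) is the fraction of samples with count > 0.
    Tables must be aligned (same taxa and samples, same order).
    """
    if ra.taxa != count.taxa or ra.samples != count.samples:
        raise ValueError("abundance and count tables must be aligned")
    return pd.DataFrame(
        {
            "taxon": ra.taxa,
            "mean_ra": ra.ra.mean(axis=1),
            "occupancy": (count.counts > 0).mean(axis=1),
        }
    )


def procrustes_m2(a: OrdinationResult, b: OrdinationResult) -> float:
    """Symmetric Procrustes residual M² between two ordinations.

    Both configurations are centered and scaled to unit sum of squares,
    then optimally rotated; the residual sum of squared distances between
    paired points is returned. Axes are truncated to the smaller count so
    M² is comparable across subset sizes.
    """
    if a.labels != b.labels:
        raise ValueError("ordinations must share sample labels and order")
    if len(a.labels) < 3:
        raise ValueError("need at least 3 samples for Procrustes analysis")
    k = min(a.coords.shape[1], b.coords.shape[1])
    try:
        _, _, m2 = _scipy_procrustes(a.coords[:, :k], b.coords[:, :k])
    except ValueError:
        # degenerate all-zero configuration: identical iff both zero
        za = not np.any(a.coords)
        zb = not np.any(b.coords)
        return 0.0 if za and zb else 1.0
    return float(m2)


def _top_set(values: np.ndarray, pct: float) -> np.ndarray:
    """Boolean mask of the top pct% values, ties at the cutoff included."""
    n = len(values)
    n_top = max(1, int(np.ceil(n * pct / 100.0)))
    cutoff = np.sort(values)[::-1][n_top - 1]
    return values >= cutoff


def sweep_select(
    count: CountTable,
    i_range: range = range(1, 21),
    j_range: range = range(1, 21),
    depth: int = 1000,
    seed: int = 42,
    mode: str = "intersection",
) -> RepSelection:
    """Sweep (i, j) abundance/occupancy cutoffs and pick the M² elbow.

    One fixed rarefaction (at `depth`) per seed keeps the M² values of
    different cells comparable. For each cell the subset table is
    renormalized, both tables' Bray-Curtis matrices are ordinated by
    PCoA, and the Procrustes M² is recorded. Cells are deduplicated by
    subset, ordered by subset size, and the cell just after the largest
    drop in M² per added taxon is returned (ties broken toward the
    smallest subset, then the smallest (i, j)).
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    table = rarefy(count, depth, seed=seed)
    ra = relative_abundance(table)
    summary = summarize_taxa(ra, table)
    mean_ra = summary["mean_ra"].to_numpy()
    occupancy = summary["occupancy"].to_numpy()
    full_ord = pcoa(bray_curtis(ra), k=ra.n_samples)

    cells: dict[frozenset, tuple[int, int, float]] = {}
    rows = []
    for i in i_range:
        top_i = _top_set(mean_ra, i)
        for j in j_range:
            top_j = _top_set(occupancy, j)
            mask = (top_i & top_j) if mode == "intersection" else (top_i | top_j)
            subset = [t for t, m in zip(table.taxa, mask) if m]
            if not subset:
                logger.warning("sweep_select: empty subset at i=%d, j=%d", i, j)
                continue
            key = frozenset(subset)
            if key in cells:
                m2 = cells[key][2]
            else:
                sub = table.select_taxa(subset)
                if (sub.counts.sum(axis=0) == 0).any():
                    logger.warning(
                        "sweep_select: subset at i=%d, j=%d empties a sample; skipped",
                        i, j)
                    continue
                sub_ord = pcoa(bray_curtis(relative_abundance(sub)),
                               k=sub.n_samples)
                m2 = procrustes_m2(full_ord, sub_ord)
                cells[key] = (i, j, m2)
            rows.append({"i": i, "j": j, "size": len(subset), "m2": m2})
    if not cells:
        raise ValueError("no (i, j) cell produced a usable subset")
    grid = pd.DataFrame(rows)

    # elbow over unique subsets ordered by size (then m2, then (i, j))
    path = sorted(
        ((len(k), v[2], v[0], v[1], k) for k, v in cells.items()),
        key=lambda t: (t[0], t[1], t[2], t[3]),
    )
    if len(path) == 1:
        size, m2, i, j, key = path[0]
        return RepSelection(i, j, sorted(key), m2, grid)
    best, best_drop = None, -np.inf
    for prev, cur in zip(path, path[1:]):
        dn = cur[0] - prev[0]
        if dn <= 0:
            continue
        drop = (prev[1] - cur[1]) / dn
        # strict improvement wins; ties keep the earlier (smaller) subset
        if drop > best_drop:
            best_drop, best = drop, cur
    if best is None:  # all subsets identical in size
        best = path[0]
    size, m2, i, j, key = best
    subset = [t for t in count.taxa if t in key]
    return RepSelection(i, j, subset, m2, grid)
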