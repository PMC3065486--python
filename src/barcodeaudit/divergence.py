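"""Divergence distributions, deep intraspecific splits, barcode-gap summaries.

Pairwise comparisons are partitioned into three classes: intraspecific
(same species), congeneric interspecific (different species, same genus)
and "other" (different genera, excluded from both distributions).  The
intra/congeneric histograms visualize the barcode gap; per-species deep
splits are flagged when single-linkage clustering of the species' specimens
at a divergence threshold (default 3%) yields two or more clusters —
equivalently, when the maximum intraspecific divergence exceeds the
threshold.  All percentages are K2P distances x 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix
from .errors import ValidationError
from .records import Dataset


def histogram(
    values: np.ndarray | list[float],
    bin_width: float = 1.0,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Left-closed right-open binning from 0 in steps of ``bin_width``.

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``;
    counts always sum to ``len(values)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size and (v < 0).any():
        raise ValidationError("histogram values must be >= 0")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    idx = np.floor(v / bin_width).astype(int) if v.size else np.array([], dtype=int)
    needed = int(idx.max()) + 1 if v.size else 1
    nb = n_bins if n_bins is not None else needed
    if needed > nb:
        raise ValidationError(f"values exceed the last of {nb} bins")
    counts = np.bincount(idx, minlength=nb) if v.size else np.zeros(nb, dtype=int)
    edges = np.arange(nb + 1) * bin_width
    return edges, counts


@dataclass(frozen=True)
class DivergenceSummary:
    """Intra/interspecific divergence distributions and per-species stats."""

    per_species: pd.DataFrame       # species, n, n_pairs, mean/max intra (%)
    intra_pct: np.ndarray           # all intraspecific pairwise divergences (%)
    congeneric_pct: np.ndarray      # all congeneric interspecific divergences (%)
    n_other_pairs: int              # cross-genus pairs (excluded from both)
    bin_width: float
    edges: np.ndarray
    intra_counts: np.ndarray
    congeneric_counts: np.ndarray

    @property
    def n_intra_pairs(self) -> int:
        return int(self.intra_pct.size)

    @property
    def n_congeneric_pairs(self) -> int:
        return int(self.congeneric_pct.size)

    @property
    def mean_intra_pct(self) -> float:
        return float(self.intra_pct.mean()) if self.intra_pct.size else float("nan")

    @property
    def mean_congeneric_pct(self) -> float:
        return float(self.congeneric_pct.mean()) if self.congeneric_pct.size else float("nan")

    @property
    def intra_range_pct(self) -> tuple[float, float]:
        if not self.intra_pct.size:
            return (float("nan"), float("nan"))
        return float(self.intra_pct.min()), float(self.intra_pct.max())

    @property
    def congeneric_range_pct(self) -> tuple[float, float]:
        if not self.congeneric_pct.size:
            return (float("nan"), float("nan"))
        return float(self.congeneric_pct.min()), float(self.congeneric_pct.max())

    def gap_table(self) -> pd.DataFrame:
        """Histogram TSV analogue: one row per bin, intra and congeneric counts."""
        return pd.DataFrame(
            {
                "bin_left_pct": self.edges[:-1],
                "bin_right_pct": self.edges[1:],
                "intraspecific": self.intra_counts,
                "congeneric_interspecific": self.congeneric_counts,
            }
        )


def divergence_summary(
    m: DistanceMatrix, d: Dataset, bin_width: float = 1.0
) -> DivergenceSummary:
    """Partition all pairwise divergences and summarize both distributions."""
    if list(m.ids) != d.ids:
        raise ValidationError("distance matrix and dataset are not aligned")
    n = len(d)
    binoms = [r.binomial for r in d.records]
    species, sp_uniques = pd.factorize(np.asarray(binoms, dtype=object))
    genus = pd.factorize(np.asarray([r.genus for r in d.records], dtype=object))[0]
    iu, ju = np.triu_indices(n, 1)
    same_sp = species[iu] == species[ju]
    same_gen = genus[iu] == genus[ju]
    dv = m.d[iu, ju] * 100.0

    intra = dv[same_sp]
    congeneric = dv[~same_sp & same_gen]
    n_other = int((~same_gen).sum())

    sp_codes = species[iu][same_sp]
    counts = pd.Series(binoms).value_counts()
    if intra.size:
        g = pd.DataFrame({"sp": sp_codes, "d": intra}).groupby("sp")["d"]
        stats = g.agg(["count", "mean", "max"])
        per_species = pd.DataFrame(
            {
                "species": [sp_uniques[i] for i in stats.index],
                "n": [int(counts[sp_uniques[i]]) for i in stats.index],
                "n_pairs": stats["count"].astype(int).values,
                "mean_intra_pct": stats["mean"].values,
                "max_intra_pct": stats["max"].values,
            }
        ).sort_values("species", ignore_index=True)
    else:
        per_species = pd.DataFrame(
            columns=["species", "n", "n_pairs", "mean_intra_pct", "max_intra_pct"]
        )

    upper = max(
        [float(intra.max()) if intra.size else 0.0,
         float(congeneric.max()) if congeneric.size else 0.0]
    )
    nb = int(np.floor(upper / bin_width)) + 1
    edges, intra_counts = histogram(intra, bin_width, n_bins=nb)
    _, cong_counts = histogram(congeneric, bin_width, n_bins=nb)
    return DivergenceSummary(
        per_species=per_species,
        intra_pct=intra,
        congeneric_pct=congeneric,
        n_other_pairs=n_other,
        bin_width=bin_width,
        edges=edges,
        intra_counts=intra_counts,
        congeneric_counts=cong_counts,
    )


def split_clusters(
    m: DistanceMatrix, members: list[str], threshold_pct: float = 3.0
) -> list[list[str]]:
    """Single-linkage partition of specimens at a divergence threshold.

    Two specimens fall in the same cluster iff they are connected by a
    chain of pairwise divergences <= threshold.  Clusters are returned in
    order of first appearance of their members.
    """
    if not members:
        raise ValidationError("empty member list")
    sub = m.submatrix(members)
    adj = sub.d <= threshold_pct / 100.0
    _, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: dict[int, list[str]] = {}
    for sid, lab in zip(members, labels):
        clusters.setdefault(int(lab), []).append(sid)
    return [clusters[k] for k in sorted(clusters, key=lambda k: members.index(clusters[k][0]))]


@dataclass(frozen=True)
class SpeciesClusterReport:
    """Deep-split report for one multi-specimen species."""

    species: str
    n: int
    cluster_sizes: tuple[int, ...]
    mean_intra_pct: float     # mean over ALL intraspecific pairs
    max_intra_pct: float
    flagged: bool

    @property
    def lineage_string(self) -> str:
        """Cluster sizes in "a/b/c" form."""
        return "/".join(str(s) for s in self.cluster_sizes)


def flag_deep_splits(
    m: DistanceMatrix, d: Dataset, threshold_pct: float = 3.0
) -> list[SpeciesClusterReport]:
    """One report per species with >= 2 specimens; flagged iff the species
    breaks into >= 2 single-linkage clusters at the threshold (strict >)."""
    reports = []
    for sp, ids in d.species_members().items():
        if len(ids) < 2:
            continue
        sub = m.submatrix(ids)
        iu = np.triu_indices(len(ids), 1)
        dv = sub.d[iu] * 100.0
        clusters = split_clusters(m, ids, threshold_pct)
        reports.append(
            SpeciesClusterReport(
                species=sp,
                n=len(ids),
                cluster_sizes=tuple(len(c) for c in clusters),
                mean_intra_pct=float(dv.mean()),
                max_intra_pct=float(dv.max()),
                flagged=len(clusters) >= 2,
            )
        )
    return reports


def deep_split_table(reports: list[SpeciesClusterReport]) -> pd.DataFrame:
    """Flagged species only, as the machine-readable deep-split table."""
    rows = [
        (r.species, r.n, r.lineage_string, round(r.mean_intra_pct, 2), r.max_intra_pct)
        for r in reports
        if r.flagged
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "n", "individuals_per_lineage", "mean_intra_pct", "max_intra_pct"],
    ).sort_values("species", ignore_index=True) if rows else pd.DataFrame(
        columns=["species", "n", "individuals_per_lineage", "mean_intra_pct", "max_intra_pct"]
    )
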