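"""Pairwise population distances, ordination, and dendrograms.

RST comes from one-level haploid AMOVA on squared repeat-count differences
summed over loci (Excoffier variance components); Nei distance is the 1972
standard distance on per-locus allele frequencies; ordination is classical
(Torgerson) metric MDS; the dendrogram is UPGMA with deterministic label
tie-breaking, exported as Newick.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np

from .forensic import allele_frequencies
from .panels import LocusPanel, PopulationSample

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "population_matrix",
    "rst_pairwise",
    "nei_standard_distance",
    "classical_mds",
    "upgma_tree",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labeled distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    method: str = ""
    panel_used: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, dest: Union[str, Path, TextIO]) -> None:
        close = False
        if isinstance(dest, (str, Path)):
            dest = open(dest, "w", encoding="utf-8")
            close = True
        try:
            dest.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.values):
                cells = "\t".join("inf" if not math.isfinite(x) else f"{x:.10g}" for x in row)
                dest.write(f"{label}\t{cells}\n")
        finally:
            if close:
                dest.close()

    @classmethod
    def from_tsv(cls, source: Union[str, Path, TextIO], method: str = "") -> "DistanceMatrix":
        close = False
        if isinstance(source, (str, Path)):
            source = open(source, encoding="utf-8")
            close = True
        try:
            lines = [ln.rstrip("\n") for ln in source if ln.strip()]
        finally:
            if close:
                source.close()
        labels = tuple(lines[0].split("\t")[1:])
        rows = []
        for ln in lines[1:]:
            cells = ln.split("\t")
            rows.append([float(c) for c in cells[1:]])
        return cls(labels, np.array(rows, dtype=float), method=method)


# ---------------------------------------------------------------------------
# repeat-score matrices
# ---------------------------------------------------------------------------

def _round_half_up_int(value: float) -> int:
    return math.floor(value + 0.5)


def population_matrix(
    sample: PopulationSample,
    loci: Sequence[str],
    drop_microvariants: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Integer repeat-score matrix (records x loci) for AMOVA-style analyses.

    Only single-copy loci are usable; records with a null or duplicated
    allele at any included locus are excluded (their ids returned for the
    exclusion log).  Microvariants are rounded half-up to the nearest
    integer by default, or the whole record dropped if requested.
    """
    rows: list[list[int]] = []
    excluded: list[str] = []
    for rec in sample.records:
        row: list[int] = []
        ok = True
        for locus in loci:
            a = rec.alleles[locus]
            if a.is_null or a.is_duplicated or len(a.values) != 1:
                ok = False
                break
            value = a.values[0]
            if a.is_microvariant and drop_microvariants:
                ok = False
                break
            row.append(_round_half_up_int(value))
        if ok:
            rows.append(row)
        else:
            excluded.append(rec.sample_id)
    return np.array(rows, dtype=float).reshape(len(rows), len(loci)), excluded


def _single_copy_loci(
    samples: Sequence[PopulationSample], panel_subset: LocusPanel | None
) -> list[str]:
    panel = panel_subset or samples[0].panel
    loci = [l.name for l in panel if l.copy_number == 1]
    if not loci:
        raise ValueError("no single-copy loci in the requested subset")
    return loci


def _ssd(matrix: np.ndarray) -> float:
    """SSD = (1/n) * sum over unordered pairs of squared Euclidean distance,
    via the per-coordinate identity sum_{i<j}(x_i-x_j)^2 = n*sum x^2 - (sum x)^2."""
    n = matrix.shape[0]
    col_sum = matrix.sum(axis=0)
    col_sq = (matrix ** 2).sum(axis=0)
    return float((n * col_sq - col_sum ** 2).sum()) / n


def rst_between(x1: np.ndarray, x2: np.ndarray) -> float:
    """RST between two populations of integer repeat-score rows."""
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs n >= 2 typed records")
    n_total = n1 + n2
    ssd_within = _ssd(x1) + _ssd(x2)
    ssd_total = _ssd(np.vstack([x1, x2]))
    df_among, df_within = 1, n_total - 2
    sigma_within = ssd_within / df_within
    msd_among = (ssd_total - ssd_within) / df_among
    n_prime = (n_total - (n1 * n1 + n2 * n2) / n_total) / df_among
    sigma_among = (msd_among - sigma_within) / n_prime
    denom = sigma_among + sigma_within
    if denom <= 0:
        return 0.0
    return min(1.0, max(0.0, sigma_among / denom))


def rst_pairwise(
    samples: Sequence[PopulationSample],
    panel_subset: LocusPanel | None = None,
    drop_microvariants: bool = False,
) -> DistanceMatrix:
    """Pairwise RST over single-copy loci (dual-copy loci excluded;
    microvariants rounded half-up; nulls/duplications drop the record)."""
    if len(samples) < 2:
        raise ValueError("need at least two populations")
    loci = _single_copy_loci(samples, panel_subset)
    matrices = []
    for s in samples:
        x, _ = population_matrix(s, loci, drop_microvariants)
        if x.shape[0] < 2:
            raise ValueError(f"population {s.name!r} has fewer than 2 usable records")
        matrices.append(x)
    k = len(samples)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = rst_between(matrices[i], matrices[j])
    return DistanceMatrix(
        tuple(s.name for s in samples),
        out,
        method="rst",
        panel_used=(panel_subset or samples[0].panel).name,
    )


# ---------------------------------------------------------------------------
# Nei standard distance
# ---------------------------------------------------------------------------

def nei_standard_distance(
    samples: Sequence[PopulationSample],
    panel_subset: LocusPanel | None = None,
) -> DistanceMatrix:
    """Nei (1972) standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)).

    The J terms are accumulated as sums over shared typed loci of the
    per-locus sums of (products of) squared allele frequencies; loci typed
    in only one population are skipped.  A zero shared identity yields +inf
    (flagged sentinel in the matrix).
    """
    if len(samples) < 2:
        raise ValueError("need at least two populations")
    loci = _single_copy_loci(samples, panel_subset)
    tables = [
        {locus: allele_frequencies(s, locus) for locus in loci} for s in samples
    ]
    k = len(samples)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            jx = jy = jxy = 0.0
            shared = 0
            for locus in loci:
                fx = tables[i][locus]
                fy = tables[j][locus]
                if fx.n_eff == 0 or fy.n_eff == 0:
                    continue
                shared += 1
                px = fx.frequencies()
                py = fy.frequencies()
                jx += sum(p * p for p in px.values())
                jy += sum(p * p for p in py.values())
                jxy += sum(p * py.get(a, 0.0) for a, p in px.items())
            if shared == 0:
                raise ValueError(
                    f"no shared typed loci between {samples[i].name!r} and {samples[j].name!r}"
                )
            if jxy == 0.0:
                d = math.inf
            else:
                d = max(0.0, -math.log(jxy / math.sqrt(jx * jy)))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(
        tuple(s.name for s in samples),
        out,
        method="nei",
        panel_used=(panel_subset or samples[0].panel).name,
    )


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    explained: np.ndarray  # per-axis fraction of positive-eigenvalue mass

    def to_tsv(self, dest: Union[str, Path, TextIO]) -> None:
        close = False
        if isinstance(dest, (str, Path)):
            dest = open(dest, "w", encoding="utf-8")
            close = True
        try:
            k = self.coordinates.shape[1]
            dest.write("label\t" + "\t".join(f"dim{i + 1}" for i in range(k)) + "\n")
            for label, row in zip(self.labels, self.coordinates):
                dest.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
        finally:
            if close:
                dest.close()


def classical_mds(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Torgerson double-centering of -D^2/2 plus eigendecomposition.

    Coordinates are the top-k eigenvectors scaled by sqrt(eigenvalue);
    negative eigenvalues are dropped with a diagnostic, and k is reduced
    (with a warning) if fewer positive eigenvalues exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dm.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("MDS requires finite distances")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-9 * max(abs(eigvals[0]), 1.0))
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; reducing MDS dimensions from {k}",
            stacklevel=2,
        )
        k = max(n_pos, 1)
    use = min(k, n_pos) if n_pos else 0
    coords = np.zeros((n, max(k, 1)))
    if use:
        coords[:, :use] = eigvecs[:, :use] * np.sqrt(eigvals[:use])
    pos_mass = eigvals[positive].sum() if n_pos else 1.0
    explained = np.array(
        [eigvals[i] / pos_mass if i < n_pos else 0.0 for i in range(coords.shape[1])]
    )
    return OrdinationResult(dm.labels, coords, eigvals, explained)


# ---------------------------------------------------------------------------
# UPGMA dendrogram
# ---------------------------------------------------------------------------

def upgma_tree(dm: DistanceMatrix) -> str:
    """UPGMA (average linkage) dendrogram as a Newick string.

    Branch lengths are ultrametric (merge height = distance/2); ties are
    broken deterministically by the lexicographically smallest pair of
    cluster leader labels.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    d = np.asarray(dm.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("UPGMA requires finite distances")

    # cluster: (leader label, newick, height, size, index list)
    clusters: list[dict] = [
        {"leader": lab, "newick": lab, "height": 0.0, "size": 1, "dist": d[i].copy()}
        for i, lab in enumerate(labels)
    ]
    # dist vectors track average distance to every *current* cluster (by position)
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dab = clusters[a]["dist"][b]
                pair = tuple(sorted((clusters[a]["leader"], clusters[b]["leader"])))
                key = (dab, pair)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dab, _), a, b = best
        ca, cb = clusters[a], clusters[b]
        height = dab / 2.0
        la = height - ca["height"]
        lb = height - cb["height"]
        children = sorted(
            [(ca["leader"], ca["newick"], la), (cb["leader"], cb["newick"], lb)]
        )
        newick = "(" + ",".join(f"{nw}:{ln:.10g}" for _, nw, ln in children) + ")"
        na, nb = ca["size"], cb["size"]
        merged_dist = (na * ca["dist"] + nb * cb["dist"]) / (na + nb)
        merged = {
            "leader": min(ca["leader"], cb["leader"]),
            "newick": newick,
            "height": height,
            "size": na + nb,
            "dist": merged_dist,
        }
        keep = [i for i in range(len(clusters)) if i not in (a, b)]
        new_clusters = [clusters[i] for i in keep] + [merged]
        # rebuild each cluster's distance vector over the new ordering
        for c in new_clusters:
            c["dist"] = np.array(
                [c["dist"][i] for i in keep]
                + [0.0 if c is merged else (na * c["dist"][a] + nb * c["dist"][b]) / (na + nb)]
            )
        merged["dist"] = np.array(
            [merged_dist[i] for i in keep] + [0.0]
        )
        clusters = new_clusters
    return clusters[0]["newick"] + ";"
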