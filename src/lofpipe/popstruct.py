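"""Population-structure analyses: PCA, 1-IBS distances, NJ trees, heterozygosity.

PCA uses the eigensoft-style normalisation (posterior allele frequency with
an add-one prior, columns scaled by sqrt(2 p (1-p))); pairwise distances are
1 minus the mean identity-by-state allele sharing; trees are built with the
Saitou-Nei neighbor-joining algorithm (Studier-Keppler Q criterion) and
written as Newick with branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable


# ---------------------------------------------------------------------------
# identity-by-state distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path, lower_triangle: bool = False) -> None:
        if lower_triangle:  # PHYLIP-compatible layout
            with open(path, "w") as fh:
                fh.write(f"{len(self.sample_ids)}\n")
                for i, sid in enumerate(self.sample_ids):
                    row = " ".join(f"{self.values[i, j]:.6f}" for j in range(i + 1))
                    fh.write(f"{sid} {row}\n".rstrip() + "\n")
        else:
            self.to_frame().to_csv(path, sep="\t")


def ibs_distance(gt: GenotypeTable) -> DistanceMatrix:
    """Pairwise 1 - IBS distance over variants non-missing in both samples.

    Per variant the allele-sharing score is 1 - |g_i - g_j| / 2; the IBS
    value is its mean and the distance is one minus that.
    """
    if gt.n_samples < 2:
        raise ValueError("need at least two samples")
    n = gt.n_samples
    D = np.zeros((n, n))
    dos = gt.dosage
    ids = list(gt.sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            if not both.any():
                raise ValueError(
                    f"samples {ids[i]!r} and {ids[j]!r} share no called variants"
                )
            share = 1.0 - np.abs(dos[i, both] - dos[j, both]) / 2.0
            D[i, j] = D[j, i] = 1.0 - share.mean()
    return DistanceMatrix(sample_ids=ids, values=D)


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coords: pd.DataFrame  # samples x PCs, columns PC1..PCk
    eigenvalues: np.ndarray  # all nonzero eigenvalues, descending
    cohorts: pd.Series = field(default=None)  # cohort label per sample


def pca_genotypes(gt: GenotypeTable, k: int = 2, posterior_freq: bool = True) -> PcaResult:
    """Top-k principal components of the normalised genotype matrix.

    Per variant the allele frequency is estimated with an add-one prior,
    p = (1 + sum g) / (2 + 2 n_called) (plain MLE with
    ``posterior_freq=False``); columns are centered and divided by
    sqrt(2 p (1-p)); missing entries become 0 after centering; monomorphic
    columns are dropped.  Component signs are stabilised so the first
    sample's coordinate is >= 0 on every component.
    """
    if gt.n_samples < 2:
        raise ValueError("need at least two samples")
    if k > gt.n_samples - 1:
        warnings.warn(
            f"k={k} clamped to n_samples-1={gt.n_samples - 1}", stacklevel=2
        )
        k = gt.n_samples - 1
    dos = gt.dosage
    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    ac = np.nansum(dos, axis=0)
    poly = np.zeros(dos.shape[1], dtype=bool)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(n_called > 0, ac / np.maximum(n_called, 1), 0.0)
        poly = (n_called > 0) & (ac > 0) & (ac < 2 * n_called)
        # also require within-sample variation (all-het columns carry none)
        poly &= np.nanstd(np.where(called, dos, np.nan), axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic variants")
    dos = dos[:, poly]
    n_called = n_called[poly]
    ac = ac[poly]
    col_mean = col_mean[poly]
    if posterior_freq:
        p_hat = (1.0 + ac) / (2.0 + 2.0 * n_called)
    else:
        p_hat = ac / (2.0 * n_called)
    M = (dos - col_mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    M = np.where(np.isnan(M), 0.0, M)

    U, s, _ = np.linalg.svd(M, full_matrices=False)
    n = gt.n_samples
    eigvals = s**2 / (n - 1)
    coords = U[:, :k] * s[:k]
    # orthogonal-invariance: stabilise signs on the first sample
    for c in range(k):
        if coords[0, c] < 0:
            coords[:, c] = -coords[:, c]
    frame = pd.DataFrame(
        coords,
        index=pd.Index(gt.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    cohorts = pd.Series(
        gt.samples["cohort"].to_numpy(), index=frame.index, name="cohort"
    )
    return PcaResult(coords=frame, eigenvalues=eigvals, cohorts=cohorts)


def detect_outliers_pca(pca: PcaResult, n_sd: float = 3.0) -> list[str]:
    """Samples whose PC1 or PC2 coordinate lies n_sd SDs from its cohort mean.

    The cohort mean and SD include the tested sample, which makes the rule
    deliberately conservative at small cohort sizes: with n samples no
    coordinate can exceed (n-1)/sqrt(n) SDs, so at the 7-sample scale this
    pipeline targets the flag list is a report, not a gatekeeper, and gross
    outliers are expected to be caught in larger merged panels.
    Flagging only — removal is a pipeline decision.
    """
    if len(pca.coords) < 3:
        raise ValueError("need at least three samples for outlier detection")
    if pca.cohorts is None:
        raise ValueError("PCA result carries no cohort labels")
    flagged: list[str] = []
    use = [c for c in ("PC1", "PC2") if c in pca.coords.columns]
    for sid in pca.coords.index:
        cohort = pca.cohorts.loc[sid]
        peers = pca.coords.loc[pca.cohorts == cohort, use]
        if len(peers) < 2:
            continue
        mean = peers.mean()
        sd = peers.std(ddof=1)
        dev = (pca.coords.loc[sid, use] - mean).abs()
        if bool((dev >= n_sd * sd).any()):
            flagged.append(sid)
    return flagged


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            inner = ",".join(
                f"{fmt(child)}:{length:.{decimals}f}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    Joins the pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j; branch
    lengths use the standard split formula with negative lengths clamped to
    zero and the deficit moved to the sister branch; ties break by
    lexicographic order of the smallest leaf label under each node.  The
    result is unrooted, with a trifurcation at the final join.
    """
    D = np.array(d.values, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")

    nodes: list[TreeNode] = [TreeNode(label=s) for s in d.sample_ids]
    keys: list[str] = list(d.sample_ids)  # smallest leaf label per active node
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if i < j else dist[(j, i)]

    next_id = n
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * get(i, j) - sums[i] - sums[j]
                lo, hi = sorted((keys[i], keys[j]))
                cand = (q, lo, hi, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = max(
                0.5 * (get(i, k) + get(j, k) - dij), 0.0
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    if len(active) == 2:
        i, j = active
        half = get(i, j) / 2.0
        root = TreeNode(children=[(nodes[i], half), (nodes[j], half)])
    else:
        i, j, k = active
        dij, dik, djk = get(i, j), get(i, k), get(j, k)
        bi = max((dij + dik - djk) / 2.0, 0.0)
        bj = max((dij + djk - dik) / 2.0, 0.0)
        bk = max((dik + djk - dij) / 2.0, 0.0)
        root = TreeNode(children=[(nodes[i], bi), (nodes[j], bj), (nodes[k], bk)])
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def observed_heterozygosity(gt: GenotypeTable) -> dict[str, float]:
    """Per-cohort mean fraction of heterozygous (dosage 1) calls per sample."""
    out: dict[str, float] = {}
    for cohort in ("A", "B"):
        dos = gt.cohort_dosage(cohort)
        if dos.shape[0] == 0:
            raise ValueError(f"cohort {cohort} is empty")
        per_sample = []
        for row in dos:
            called = row[~np.isnan(row)]
            per_sample.append(np.nan if called.size == 0 else (called == 1).mean())
        out[cohort] = float(np.nanmean(per_sample))
    return out
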