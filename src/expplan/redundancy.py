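"""Information redundancy between datasets.

Two datasets are redundant for functional annotation when they induce
similar co-expression structure over functionally labeled gene pairs.  For
each dataset the Fisher z-transformed Pearson correlation z = atanh(r) is
computed for every gene pair with a defined functional-relationship (FR)
label; the overlap between two datasets is then the conditional mutual
information (in bits) between their binned z-value distributions given FR:

    I(X;Y|FR) = sum_fr p(fr) * sum_ab p(a,b|fr) log2[ p(a,b|fr) /
                                                      (p(a|fr) p(b|fr)) ]

Conditioning on FR discounts the part of the dependence that merely reflects
how many related vs unrelated pairs the two datasets happen to share, keeping
only the functionally informative overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gold_standard import FR_TRUE, FR_FALSE, FunctionalRelationLabels

__all__ = [
    "BinSpec",
    "PairCorrelationProfile",
    "CMIMatrix",
    "pair_z_correlations",
    "conditional_mutual_information",
    "cmi_matrix",
]

#: Pearson r is clamped to +/- this value before atanh so z stays finite
R_CLAMP = 0.999999


@dataclass(frozen=True)
class BinSpec:
    """Equal-width binning of z values over a clipped range."""

    n_bins: int = 20
    lo: float = -3.0
    hi: float = 3.0

    def __post_init__(self) -> None:
        if self.n_bins < 2 or not self.lo < self.hi:
            raise ValueError("invalid bin specification")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_bins + 1)

    def digitize(self, z: np.ndarray) -> np.ndarray:
        clipped = np.clip(z, self.lo, self.hi)
        idx = np.digitize(clipped, self.edges[1:-1])
        return idx


@dataclass
class PairCorrelationProfile:
    """Per-gene-pair z-transformed correlations for one dataset.

    ``pairs`` holds (gene_a, gene_b) name tuples (a < b) aligned with
    ``z_values`` and ``fr`` labels.
    """

    dataset_id: str
    pairs: list[tuple[str, str]]
    z_values: np.ndarray
    fr: np.ndarray

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.fr = np.asarray(self.fr, dtype=np.int8)
        if not np.isfinite(self.z_values).all():
            raise ValueError("z values must be finite")


@dataclass
class CMIMatrix:
    """Symmetric datasets x datasets conditional-mutual-information table."""

    values: pd.DataFrame
    bin_spec: BinSpec
    pair_counts: pd.DataFrame

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.values.index)


def pair_z_correlations(
    ds,
    fr_labels: FunctionalRelationLabels,
    pair_subset: list[tuple[str, str]] | None = None,
    log: dict | None = None,
) -> PairCorrelationProfile:
    """z-transformed Pearson correlations for the FR-defined pairs in a dataset.

    Only pairs whose genes are both present in the dataset are retained;
    genes with zero variance across arrays are dropped (their pairs are
    logged).  Requires at least 3 arrays.
    """
    if ds.n_arrays < 3:
        raise ValueError(f"{ds.dataset_id}: need >=3 arrays for correlations")
    gene_pos = ds.gene_index()
    fr_idx = {g: i for i, g in enumerate(fr_labels.genes)}

    if pair_subset is None:
        common = [g for g in fr_labels.genes if g in gene_pos]
        ci = np.array([fr_idx[g] for g in common])
        sub_fr = fr_labels.matrix[np.ix_(ci, ci)]
        iu = np.triu_indices(len(common), k=1)
        defined = sub_fr[iu] >= 0
        pair_names = [
            (common[a], common[b])
            for a, b in zip(iu[0][defined], iu[1][defined])
        ]
        fr_vals = sub_fr[iu][defined]
    else:
        pair_names, fr_list = [], []
        for a, b in pair_subset:
            if a in gene_pos and b in gene_pos and a in fr_idx and b in fr_idx:
                lab = fr_labels.matrix[fr_idx[a], fr_idx[b]]
                if lab >= 0:
                    pair_names.append((a, b) if a < b else (b, a))
                    fr_list.append(lab)
        fr_vals = np.array(fr_list, dtype=np.int8)

    X = ds.values
    sd = X.std(axis=1)
    ok_gene = sd > 0
    keep, dropped = [], 0
    for k, (a, b) in enumerate(pair_names):
        if ok_gene[gene_pos[a]] and ok_gene[gene_pos[b]]:
            keep.append(k)
        else:
            dropped += 1
    if log is not None and dropped:
        log["zero_variance_pairs_dropped"] = (
            log.get("zero_variance_pairs_dropped", 0) + dropped
        )
    pair_names = [pair_names[k] for k in keep]
    fr_vals = fr_vals[keep]

    centered = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    ia = np.array([gene_pos[a] for a, _ in pair_names], dtype=int)
    ib = np.array([gene_pos[b] for _, b in pair_names], dtype=int)
    r = (centered[ia] * centered[ib]).sum(axis=1) / (norm[ia] * norm[ib])
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    return PairCorrelationProfile(
        dataset_id=ds.dataset_id,
        pairs=pair_names,
        z_values=np.arctanh(r),
        fr=fr_vals,
    )


def _stratum_mi(joint: np.ndarray) -> float:
    """Mutual information (bits) of a joint count/probability table."""
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def conditional_mutual_information(
    px: PairCorrelationProfile,
    py: PairCorrelationProfile,
    bins: BinSpec = BinSpec(),
    min_pairs_per_stratum: int = 500,
) -> float | None:
    """CMI (bits) between two datasets' z-profiles given the FR label.

    Estimated from joint histograms of binned z values over the gene pairs
    common to both profiles; p(fr) is the empirical mixture weight of the
    common-pair set.  Returns None (undefined) when either FR stratum has
    fewer than ``min_pairs_per_stratum`` common pairs.  Negative estimates
    are clipped to 0.  The estimate is symmetric in the two profiles
    bit-exactly (arguments are canonicalized by dataset id).
    """
    if py.dataset_id < px.dataset_id:
        px, py = py, px
    idx_y = {p: k for k, p in enumerate(py.pairs)}
    kx, ky = [], []
    for k, p in enumerate(px.pairs):
        j = idx_y.get(p)
        if j is not None:
            kx.append(k)
            ky.append(j)
    if not kx:
        return None
    zx = px.z_values[kx]
    zy = py.z_values[ky]
    fr = px.fr[kx]

    total = len(zx)
    cmi = 0.0
    for stratum in (FR_FALSE, FR_TRUE):
        sel = fr == stratum
        n = int(sel.sum())
        if n < min_pairs_per_stratum:
            return None
        bx = bins.digitize(zx[sel])
        by = bins.digitize(zy[sel])
        joint = np.zeros((bins.n_bins, bins.n_bins))
        np.add.at(joint, (bx, by), 1.0)
        cmi += (n / total) * _stratum_mi(joint)
    return max(cmi, 0.0)


def cmi_matrix(
    compendium,
    fr_labels: FunctionalRelationLabels,
    bins: BinSpec = BinSpec(),
    max_pairs: int = 200_000,
    min_pairs_per_stratum: int = 500,
    seed: int = 0,
    log: dict | None = None,
) -> CMIMatrix:
    """All-pairs CMI over a compendium, symmetric by construction.

    The FR-defined pair set is subsampled uniformly (seeded) to at most
    ``max_pairs`` pairs, shared by every dataset so all entries use a common
    pair universe.  The diagonal holds the self-CMI H(X_binned | FR).
    Undefined entries (insufficient common pairs) are NaN.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(fr_labels.genes), k=1)
    defined = fr_labels.matrix[iu] >= 0
    all_pairs = [
        (fr_labels.genes[a], fr_labels.genes[b])
        for a, b in zip(iu[0][defined], iu[1][defined])
    ]
    if len(all_pairs) > max_pairs:
        pick = rng.choice(len(all_pairs), size=max_pairs, replace=False)
        all_pairs = [all_pairs[k] for k in sorted(pick)]

    profiles = [
        pair_z_correlations(ds, fr_labels, pair_subset=all_pairs, log=log)
        for ds in compendium
    ]
    ids = [p.dataset_id for p in profiles]
    vals = pd.DataFrame(np.nan, index=ids, columns=ids)
    counts = pd.DataFrame(0, index=ids, columns=ids)
    for i, pi in enumerate(profiles):
        for j in range(i, len(profiles)):
            pj = profiles[j]
            common = len(set(pi.pairs) & set(pj.pairs))
            c = conditional_mutual_information(pi, pj, bins, min_pairs_per_stratum)
            vals.iloc[i, j] = vals.iloc[j, i] = np.nan if c is None else c
            counts.iloc[i, j] = counts.iloc[j, i] = common
    return CMIMatrix(values=vals, bin_spec=bins, pair_counts=counts)
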