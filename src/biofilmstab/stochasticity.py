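"""Phylogenetic null-model analysis of community assembly.

betaMNTD is the abundance-weighted mean phylogenetic distance from each
genome in one community to its nearest relative in the other.  Comparing
the observed betaMNTD of a plot pair with a null distribution obtained by
shuffling tip labels across the phylogeny yields betaNTI (a standardised
effect size) and, through the normalised-stochasticity construction, a
pairwise stochasticity fraction NST in [0, 1]: values near 1 mean assembly
indistinguishable from the phylogeny-random null, values near 0 mean
strongly deterministic convergence or divergence.  Group summaries average
the n(n-1)/2 pairwise values among the plots of one treatment x date group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UndefinedSampleError, ValidationError

__all__ = [
    "patristic_matrix",
    "beta_mntd",
    "null_randomize",
    "beta_nti",
    "nst_group",
    "nst_bootstrap_compare",
    "fdr_adjust",
    "NstResult",
    "nst_by_group",
]


def patristic_matrix(tree) -> tuple[np.ndarray, list[str]]:
    """Dense tip-to-tip patristic distance matrix from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            D[i, j] = D[j, i] = d
    return D, labels


def _align(comm: np.ndarray | dict, labels: list[str]) -> np.ndarray:
    if isinstance(comm, dict):
        missing = sorted(set(comm) - set(labels))
        if missing:
            raise ValidationError(f"taxa missing from tree: {', '.join(missing)}")
        v = np.zeros(len(labels))
        for i, lab in enumerate(labels):
            v[i] = comm.get(lab, 0.0)
        return v
    v = np.asarray(comm, dtype=float)
    if v.shape != (len(labels),):
        raise ValidationError("community vector length does not match tree tips")
    return v


def _beta_mntd_from_matrix(
    D: np.ndarray, x: np.ndarray, y: np.ndarray, abundance_weighted: bool = True
) -> float:
    I = np.flatnonzero(x > 0)
    J = np.flatnonzero(y > 0)
    if I.size == 0 or J.size == 0:
        raise UndefinedSampleError("empty community in betaMNTD")
    sub = D[np.ix_(I, J)]
    min_i = sub.min(axis=1)  # nearest neighbour in J for each i
    min_j = sub.min(axis=0)
    if abundance_weighted:
        p = x[I] / x[I].sum()
        q = y[J] / y[J].sum()
    else:
        p = np.full(I.size, 1.0 / I.size)
        q = np.full(J.size, 1.0 / J.size)
    return 0.5 * (float(np.dot(p, min_i)) + float(np.dot(q, min_j)))


def beta_mntd(comm_i, comm_j, tree=None, abundance_weighted: bool = True,
              dist: np.ndarray | None = None, labels: list[str] | None = None) -> float:
    """Between-community mean nearest-taxon distance.

    Communities may be dicts keyed by tip label or vectors aligned to
    ``labels``.  Pass ``dist``/``labels`` to reuse a precomputed patristic
    matrix; otherwise they are derived from ``tree``.
    """
    if dist is None or labels is None:
        if tree is None:
            raise ValueError("either a tree or a precomputed distance matrix is required")
        dist, labels = patristic_matrix(tree)
    x = _align(comm_i, labels)
    y = _align(comm_j, labels)
    return _beta_mntd_from_matrix(dist, x, y, abundance_weighted)


def null_randomize(
    dist: np.ndarray,
    communities: np.ndarray,
    n_rand: int,
    seed: int,
    abundance_weighted: bool = True,
) -> np.ndarray:
    """Null betaMNTD distributions under whole-tree tip-label shuffles.

    ``communities`` is a plot x taxon abundance matrix aligned to ``dist``.
    Each randomisation permutes taxon positions on the phylogeny (rows and
    columns of the distance matrix) while community composition stays fixed;
    all plot pairs share the same permutation within a randomisation.

    Returns an array of shape (n_rand, n_pairs) with pairs in
    ``itertools.combinations`` order.
    """
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    if dist.shape[0] < 2:
        raise ValidationError("degenerate tree: need at least 2 tips")
    comm = np.asarray(communities, dtype=float)
    n_plots, S = comm.shape
    if S != dist.shape[0]:
        raise ValidationError("community matrix does not match distance matrix")
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for a in range(n_plots) for b in range(a + 1, n_plots)]
    out = np.empty((n_rand, len(pairs)))
    for r in range(n_rand):
        perm = rng.permutation(S)
        Dp = dist[np.ix_(perm, perm)]
        for k, (a, b) in enumerate(pairs):
            out[r, k] = _beta_mntd_from_matrix(Dp, comm[a], comm[b], abundance_weighted)
    return out


def beta_nti(observed: float, null_mean: float, null_sd: float) -> float:
    """Standardised effect size (observed - null mean) / null SD.

    A zero null SD leaves the index undefined; NaN is returned and callers
    exclude it from downstream summaries.
    """
    if null_sd < 0:
        raise ValueError("null_sd must be non-negative")
    if null_sd == 0:
        return float("nan")
    return (observed - null_mean) / null_sd


def _nst_values(obs: np.ndarray, null_mean: np.ndarray, dmax: float) -> np.ndarray:
    """Pairwise stochasticity fractions from scaled observed/null dissimilarity."""
    if dmax <= 0:
        # all communities identical and co-located on the tree: nothing to
        # normalise; no deviation from null is detectable
        return np.ones_like(obs)
    d = np.clip(obs / dmax, 0.0, 1.0)
    e = np.clip(null_mean / dmax, 1e-12, 1.0 - 1e-12)
    ss = np.where(d >= e, (d - e) / (1.0 - e), (e - d) / e)
    nst = np.clip(1.0 - ss, 0.0, 1.0)
    # communities sharing their full taxon set have betaMNTD 0 under every
    # tip shuffle: observed and null agree, so no deviation is detectable
    degenerate = (obs <= 1e-12 * dmax) & (null_mean <= 1e-12 * dmax)
    nst[degenerate] = 1.0
    return nst


@dataclass
class NstResult:
    """Pairwise and group-level normalised stochasticity for one group."""

    group: str
    pairwise_values: np.ndarray  # NST in [0, 1], length n(n-1)/2
    betanti: np.ndarray  # same pair order; NaN where null SD = 0
    n_randomizations: int
    observed_bmntd: np.ndarray = field(default=None, repr=False)
    null_mean: np.ndarray = field(default=None, repr=False)
    null_sd: np.ndarray = field(default=None, repr=False)

    @property
    def group_mean(self) -> float:
        return float(np.mean(self.pairwise_values))


def nst_group(
    communities: np.ndarray,
    dist: np.ndarray,
    n_rand: int = 1000,
    seed: int = 0,
    abundance_weighted: bool = True,
    group: str = "",
    dmax: float | None = None,
) -> NstResult:
    """Pairwise NST among the plots of one group, plus betaNTI.

    Dissimilarities (observed and null) are scaled to [0, 1] by the maximum
    attainable betaMNTD over the taxon pool — the tree diameter, reached by
    two single-taxon communities at the deepest split (pass ``dmax`` to
    override).  For each pair, with scaled observed d and scaled null
    expectation e: stochasticity is 1 - (d - e)/(1 - e) when d >= e
    (deterministic divergence) and 1 - (e - d)/e when d < e (deterministic
    convergence), clamped to [0, 1].
    """
    comm = np.asarray(communities, dtype=float)
    n_plots = comm.shape[0]
    if n_plots < 2:
        raise InsufficientDataError("NST needs at least 2 plots per group")
    pairs = [(a, b) for a in range(n_plots) for b in range(a + 1, n_plots)]
    obs = np.array(
        [_beta_mntd_from_matrix(dist, comm[a], comm[b], abundance_weighted) for a, b in pairs]
    )
    null = null_randomize(dist, comm, n_rand, seed, abundance_weighted)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    bnti = np.array([beta_nti(o, m, s) for o, m, s in zip(obs, null_mean, null_sd)])

    if dmax is None:
        dmax = float(np.max(dist))
    nst = _nst_values(obs, null_mean, dmax)
    return NstResult(
        group=group,
        pairwise_values=nst,
        betanti=bnti,
        n_randomizations=n_rand,
        observed_bmntd=obs,
        null_mean=null_mean,
        null_sd=null_sd,
    )


def nst_bootstrap_compare(
    result_a: NstResult | np.ndarray,
    result_b: NstResult | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    side: str = "auto",
) -> float:
    """Bootstrap p-value for a difference in group-mean NST.

    Pairwise values are resampled with replacement within each group and the
    p-value is the fraction of bootstrap replicates whose mean difference
    contradicts the tested ordering (ties count as contradiction), floored
    at 1/(n_boot+1).  ``side`` fixes the one-sided hypothesis: ``greater``
    tests mean(a) > mean(b), ``less`` the reverse, ``auto`` takes the
    observed ordering (note the direction is then chosen post hoc, so
    rejecting at alpha carries a ~2*alpha type-I rate), and ``two-sided``
    doubles the auto p and caps at 1.
    """
    a = result_a.pairwise_values if isinstance(result_a, NstResult) else np.asarray(result_a, float)
    b = result_b.pairwise_values if isinstance(result_b, NstResult) else np.asarray(result_b, float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("empty group in bootstrap comparison")
    if side not in ("auto", "greater", "less", "two-sided"):
        raise ValueError(f"unknown side {side!r}")
    rng = np.random.default_rng(seed)
    if side == "greater":
        sign = 1.0
    elif side == "less":
        sign = -1.0
    else:
        sign = np.sign(a.mean() - b.mean()) or 1.0
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    contra = np.mean(sign * diffs <= 0)
    p = max(float(contra), 1.0 / (n_boot + 1))
    if side == "two-sided":
        p = min(1.0, 2 * p)
    return p


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a p-value family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nst_by_group(
    community: pd.DataFrame,
    dist: np.ndarray,
    labels: list[str],
    n_rand: int = 1000,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> tuple[pd.DataFrame, dict[str, NstResult]]:
    """NST per treatment x date group of a long-format community table."""
    from .config import UNBINNED_ID

    community = community[community["mag_id"] != UNBINNED_ID]
    label_index = {lab: i for i, lab in enumerate(labels)}
    missing = sorted(set(community["mag_id"]) - set(labels))
    if missing:
        raise ValidationError(f"taxa missing from tree: {', '.join(missing)}")
    # first pass: observed and null dissimilarities per treatment x date group
    groups = []
    for gi, ((treat, date), sub) in enumerate(
        community.groupby(["treatment", "date"], sort=True)
    ):
        plots = sorted(sub["plot_id"].unique())
        if len(plots) < 2:
            continue
        comm = np.zeros((len(plots), len(labels)))
        for pi, plot in enumerate(plots):
            psub = sub[sub["plot_id"] == plot]
            comm[pi, [label_index[m] for m in psub["mag_id"]]] = psub["tpm"].to_numpy()
        pairs = [(a, b) for a in range(len(plots)) for b in range(a + 1, len(plots))]
        obs = np.array(
            [_beta_mntd_from_matrix(dist, comm[a], comm[b], abundance_weighted) for a, b in pairs]
        )
        null = null_randomize(dist, comm, n_rand, seed + gi, abundance_weighted)
        groups.append((treat, date, plots, obs, null))
    if not groups:
        return pd.DataFrame(), {}
    # second pass: one dataset-wide scaling constant (the attainable maximum)
    dmax = float(np.max(dist))
    rows, results = [], {}
    for treat, date, plots, obs, null in groups:
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1)
        bnti = np.array([beta_nti(o, m, s) for o, m, s in zip(obs, null_mean, null_sd)])
        res = NstResult(
            group=f"{treat}@{date}",
            pairwise_values=_nst_values(obs, null_mean, dmax),
            betanti=bnti,
            n_randomizations=n_rand,
            observed_bmntd=obs,
            null_mean=null_mean,
            null_sd=null_sd,
        )
        results[res.group] = res
        rows.append(
            {
                "treatment": treat,
                "date": date,
                "n_plots": len(plots),
                "n_pairs": len(res.pairwise_values),
                "nst_mean_pct": 100.0 * res.group_mean,
                "betanti_mean": (
                    float(np.nanmean(res.betanti))
                    if np.isfinite(res.betanti).any()
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows), results
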