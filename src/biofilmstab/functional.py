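"""Functional structure from stress-tolerance trait combinations.

Genomes sharing the same combination (binary presence profile) of
stress-tolerance gene modules form a functional entity (FE).  From the FE
partition of a community we derive functional-group richness (FR, the
number of FEs), functional over-redundancy (FOR, the share of genomes in
excess within FEs filled above the mean level S/K) and functional
vulnerability (FVuln, the share of FEs held by a single genome).  Community
weighted means (e.g. of the minimal doubling time, CWMDT) summarise the
growth-strategy composition, and a variance-modelled regression quantifies
the tolerance-growth trade-off across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import UNBINNED_ID
from .errors import ValidationError

__all__ = [
    "FunctionalEntityPartition",
    "FunctionalMetrics",
    "assign_functional_entities",
    "functional_metrics",
    "community_weighted_trait",
    "tradeoff_regression",
    "functional_table",
    "cwm_table",
]


@dataclass(frozen=True)
class FunctionalEntityPartition:
    """Equivalence classes of identical stress-tolerance trait profiles."""

    assignment: dict[str, str]  # mag_id -> fe_id
    fe_sizes: dict[str, int] = field(repr=False)

    @property
    def S(self) -> int:
        return len(self.assignment)

    @property
    def K(self) -> int:
        return len(self.fe_sizes)


@dataclass(frozen=True)
class FunctionalMetrics:
    FR: int
    FOR: float
    FVuln: float


def _trait_profile_columns(traits: pd.DataFrame) -> list[str]:
    cols = [c for c in traits.columns if c.startswith("module_")]
    if cols:
        return cols
    if "stress_module_count" in traits.columns:
        return ["stress_module_count"]
    raise ValidationError("trait table has neither module_* columns nor stress_module_count")


def assign_functional_entities(
    traits: pd.DataFrame, present_mags=None
) -> FunctionalEntityPartition:
    """Group genomes by their binarised stress-module profile.

    The profile is presence/absence over the module columns (count > 0 means
    present).  FE identifiers are assigned in lexicographic order of the
    binary profiles, so the partition is deterministic.
    """
    t = traits.set_index("mag_id") if "mag_id" in traits.columns else traits
    if present_mags is None:
        present = list(t.index)
    else:
        present = list(present_mags)
        missing = sorted(set(present) - set(t.index))
        if missing:
            raise ValidationError(f"traits missing for MAGs: {', '.join(missing)}")
    if not present:
        raise ValidationError("empty community: no functional entities")
    cols = _trait_profile_columns(t)
    profiles = (t.loc[present, cols].to_numpy() > 0).astype(int)
    keys = ["".join(map(str, row)) for row in profiles]
    unique = sorted(set(keys))
    width = max(3, len(str(len(unique))))
    fe_of_key = {k: f"fe_{i + 1:0{width}d}" for i, k in enumerate(unique)}
    assignment = {mag: fe_of_key[k] for mag, k in zip(present, keys)}
    sizes: dict[str, int] = {}
    for fe in assignment.values():
        sizes[fe] = sizes.get(fe, 0) + 1
    return FunctionalEntityPartition(assignment=assignment, fe_sizes=sizes)


def functional_metrics(partition: FunctionalEntityPartition) -> FunctionalMetrics:
    """FR, FOR and FVuln from an FE partition.

    FOR = (1/S) * sum_k max(0, n_k - S/K): the proportion of genomes in
    excess of the mean fill level within over-filled FEs.  FVuln is the
    proportion of FEs represented by a single genome.
    """
    sizes = np.array(list(partition.fe_sizes.values()), dtype=float)
    if sizes.size == 0:
        raise ValidationError("empty partition")
    S, K = partition.S, partition.K
    mean_fill = S / K
    over = float(np.sum(np.clip(sizes - mean_fill, 0.0, None))) / S
    vuln = float(np.sum(sizes == 1)) / K
    return FunctionalMetrics(FR=K, FOR=over, FVuln=vuln)


def community_weighted_trait(abundances, trait_values) -> float:
    """Abundance-weighted mean trait over genomes with positive abundance."""
    x = np.asarray(abundances, dtype=float)
    t = np.asarray(trait_values, dtype=float)
    if x.shape != t.shape:
        raise ValidationError("abundance and trait vectors differ in length")
    keep = x > 0
    if not keep.any():
        raise ValidationError("no genome with positive abundance")
    if np.any(~np.isfinite(t[keep])):
        raise ValidationError("missing trait value for a present genome")
    p = x[keep] / x[keep].sum()
    return float(np.dot(p, t[keep]))


# ---------------------------------------------------------------------------
# tolerance-growth trade-off


@dataclass(frozen=True)
class TradeoffFit:
    """Two-stage variance-modelled regression of log-MDT on stress modules."""

    slope: float
    se: float
    z: float
    p: float
    params: pd.Series
    variance_params: pd.Series
    n_iter: int
    converged: bool


def tradeoff_regression(
    traits: pd.DataFrame,
    subset=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> TradeoffFit:
    """Regress log minimal doubling time on the stress-module count.

    Genome size and completeness enter as covariates; the residual variance
    is modelled log-linearly in log genome size.  The mean model is fit by
    weighted least squares and the variance model by least squares on log
    squared residuals, iterated to convergence.  The reported Wald z tests
    the stress-module coefficient.
    """
    t = traits if subset is None else traits[traits["mag_id"].isin(set(subset))]
    if len(t) < 5:
        raise ValidationError("trade-off regression needs at least 5 genomes")
    if (t["mdt"] <= 0).any() or (t["genome_size"] <= 0).any():
        raise ValidationError("MDT and genome size must be positive")
    y = np.log(t["mdt"].to_numpy(dtype=float))
    X = pd.DataFrame(
        {
            "stress_module_count": t["stress_module_count"].to_numpy(dtype=float),
            "genome_size_mb": t["genome_size"].to_numpy(dtype=float) / 1e6,
            "completeness": t["completeness"].to_numpy(dtype=float),
        }
    )
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValidationError(f"constant predictor: {col}")
    Xd = sm.add_constant(X)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise ValidationError("collinear predictors in trade-off design")
    log_gs = np.log(t["genome_size"].to_numpy(dtype=float))
    Zv = sm.add_constant(pd.DataFrame({"log_genome_size": log_gs}))

    weights = np.ones_like(y)
    beta_old = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        fit = sm.WLS(y, Xd, weights=weights).fit()
        resid2 = np.clip(fit.resid**2, 1e-12, None)
        vfit = sm.OLS(np.log(resid2), Zv).fit()
        sigma2 = np.exp(vfit.fittedvalues)
        weights = 1.0 / sigma2
        beta = fit.params.to_numpy()
        if beta_old is not None and np.max(np.abs(beta - beta_old)) < tol:
            converged = True
            break
        beta_old = beta
    slope = float(fit.params["stress_module_count"])
    se = float(fit.bse["stress_module_count"])
    z = slope / se
    from scipy.stats import norm

    p = float(2 * norm.sf(abs(z)))
    return TradeoffFit(
        slope=slope,
        se=se,
        z=z,
        p=p,
        params=fit.params,
        variance_params=vfit.params,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# table-level drivers


def functional_table(
    community: pd.DataFrame, traits: pd.DataFrame, presence_threshold: float = 0.0
) -> pd.DataFrame:
    """FR/FOR/FVuln per plot x date, on genomes with TPM above threshold."""
    community = community[community["mag_id"] != UNBINNED_ID]
    rows = []
    for (plot, treat, date), sub in community.groupby(
        ["plot_id", "treatment", "date"], sort=True
    ):
        present = sub.loc[sub["tpm"] > presence_threshold, "mag_id"]
        part = assign_functional_entities(traits, present)
        m = functional_metrics(part)
        rows.append(
            {
                "plot_id": plot,
                "treatment": treat,
                "date": date,
                "FR": m.FR,
                "FOR": m.FOR,
                "FVuln": m.FVuln,
            }
        )
    return pd.DataFrame(rows)


def cwm_table(
    community: pd.DataFrame, traits: pd.DataFrame, trait: str = "mdt"
) -> pd.DataFrame:
    """Community-weighted mean of a genome trait per plot x date."""
    community = community[community["mag_id"] != UNBINNED_ID]
    tmap = traits.set_index("mag_id")[trait]
    rows = []
    for (plot, treat, date), sub in community.groupby(
        ["plot_id", "treatment", "date"], sort=True
    ):
        vals = tmap.reindex(sub["mag_id"]).to_numpy()
        rows.append(
            {
                "plot_id": plot,
                "treatment": treat,
                "date": date,
                f"cwm_{trait}": community_weighted_trait(sub["tpm"].to_numpy(), vals),
            }
        )
    return pd.DataFrame(rows)
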