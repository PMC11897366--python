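"""Taxonomic diversity and within-plot population dynamics.

Hill numbers of order q express diversity as an effective number of equally
abundant genomes: q=0 is richness, q=1 the exponential of Shannon entropy,
q=2 the inverse Simpson concentration.  Synchrony among genome trajectories
within a plot is Gross' eta — the abundance-weighted mean correlation
between each genome's trajectory and the summed trajectory of all others —
and population variability is the abundance-weighted mean temporal SD of
each genome's abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import UNBINNED_ID
from .errors import InsufficientDataError, UndefinedSampleError

__all__ = [
    "hill_number",
    "gross_synchrony_weighted",
    "population_variability_weighted",
    "diversity_table",
    "synchrony_table",
]


def hill_number(abundances, q: float) -> float:
    """Effective number of genomes of order ``q``.

    Zero abundances are dropped before normalisation.  q may be any
    non-negative real; q=1 is the exponential-Shannon limit.
    """
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise ValueError("abundances must be a 1-D vector")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    if q < 0:
        raise ValueError("q must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise UndefinedSampleError("all-zero abundance vector: diversity undefined")
    p = x / x.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def _trajectory_weights(traj: np.ndarray) -> np.ndarray:
    """Mean relative abundance of each genome across dates, summing to 1."""
    totals = traj.sum(axis=0)
    if np.any(totals <= 0):
        raise UndefinedSampleError("a date with zero total abundance")
    rel = traj / totals
    w = rel.mean(axis=1)
    return w / w.sum()


def _as_matrix(trajectories) -> np.ndarray:
    m = np.asarray(trajectories, dtype=float)
    if m.ndim != 2:
        raise ValueError("trajectories must be a genome x date matrix")
    return m


def gross_synchrony_weighted(trajectories) -> float:
    """Gross' eta for one plot: weighted mean corr(y_i, sum_{j!=i} y_j).

    ``trajectories`` is a genome x date matrix of TPM abundances.  Weights
    are mean relative abundances over the plot's dates; genomes with a
    constant trajectory carry no defined correlation and are excluded, their
    weight mass renormalised over the rest.
    """
    m = _as_matrix(trajectories)
    if m.shape[1] < 3:
        raise InsufficientDataError("synchrony needs at least 3 dates")
    w = _trajectory_weights(m)
    sd = m.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() == 0:
        raise UndefinedSampleError("all trajectories constant: synchrony undefined")
    total = m.sum(axis=0)
    etas, weights = [], []
    for i in np.flatnonzero(keep):
        rest = total - m[i]
        if np.std(rest, ddof=1) == 0:
            continue
        r = np.corrcoef(m[i], rest)[0, 1]
        etas.append(r)
        weights.append(w[i])
    if not weights:
        raise UndefinedSampleError("no genome pair with variable complement")
    weights = np.asarray(weights) / np.sum(weights)
    return float(np.clip(np.dot(weights, etas), -1.0, 1.0))


def population_variability_weighted(trajectories) -> float:
    """Weighted mean temporal SD (n-1 denominator) of each genome's TPM."""
    m = _as_matrix(trajectories)
    if m.shape[1] < 2:
        raise InsufficientDataError("population variability needs at least 2 dates")
    w = _trajectory_weights(m)
    return float(np.dot(w, m.std(axis=1, ddof=1)))


# ---------------------------------------------------------------------------
# table-level drivers over a long-format community table; the unbinned
# pseudo-taxon (non-MAG reads) is excluded from all genome-level statistics


def _mag_rows(community: pd.DataFrame) -> pd.DataFrame:
    return community[community["mag_id"] != UNBINNED_ID]


def _plot_matrix(sub: pd.DataFrame) -> np.ndarray:
    wide = sub.pivot_table(index="mag_id", columns="date", values="tpm", fill_value=0.0)
    return wide.to_numpy(dtype=float)


def diversity_table(community: pd.DataFrame, q_values=(0, 1, 2)) -> pd.DataFrame:
    """Per plot x date Hill numbers; tidy output with one row per q."""
    community = _mag_rows(community)
    rows = []
    for (plot, treat, date), sub in community.groupby(
        ["plot_id", "treatment", "date"], sort=True
    ):
        for q in q_values:
            rows.append(
                {
                    "plot_id": plot,
                    "treatment": treat,
                    "date": date,
                    "q": q,
                    "value": hill_number(sub["tpm"].to_numpy(), q),
                }
            )
    return pd.DataFrame(rows)


def synchrony_table(community: pd.DataFrame) -> pd.DataFrame:
    """Per-plot Gross' eta and weighted population variability."""
    community = _mag_rows(community)
    rows = []
    for (plot, treat), sub in community.groupby(["plot_id", "treatment"], sort=True):
        m = _plot_matrix(sub)
        rows.append(
            {
                "plot_id": plot,
                "treatment": treat,
                "eta": gross_synchrony_weighted(m),
                "pop_variability": population_variability_weighted(m),
            }
        )
    return pd.DataFrame(rows)
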