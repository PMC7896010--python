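"""Population-level quantification of recurrent inhibition.

Connection strength is summarized three ways: *amplitude* (mean IPSP height
over motoneurons showing an effect), *incidence* (percentage of measurable
motoneurons with an effect), and their product amplitude x incidence — which
is identical to the mean amplitude counting non-responding motoneurons as
zero. Confidence intervals come from bootstrap resampling of motoneurons,
category differences from a Monte-Carlo draw of same-sized subsets from the
full cohort, proportions from an exact binomial test (tail doubling), and
multiple comparisons are controlled with the Benjamini-Hochberg step-up
procedure (acceptance flags only; no adjusted p-values).

Records flagged ``measurable=False`` (an antidromic spike obscured the IPSP,
typical of homonymous combinations) are excluded from every measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from renshaw._rng import child_rng
from renshaw.errors import ConfigurationError

__all__ = [
    "ConnectionRecord",
    "PopulationMeasure",
    "records_to_frame",
    "motoneuron_table",
    "population_measures",
    "bootstrap_ci",
    "permutation_category_test",
    "binomial_proportion_test",
    "benjamini_hochberg",
]

Measure = Literal["amplitude", "incidence", "product"]


@dataclass(frozen=True)
class ConnectionRecord:
    """One tested motoneuron-nerve combination."""

    motoneuron_id: str
    category: str
    nerve: str
    amplitude_uv: float      # 0 if undetected
    detected: bool
    measurable: bool = True

    def __post_init__(self) -> None:
        if self.detected and self.amplitude_uv < 50.0:
            raise ConfigurationError("detected records must have amplitude >= 50 µV")


@dataclass(frozen=True)
class PopulationMeasure:
    amplitude_uv: float      # mean over detected units (0 if none detected)
    incidence_pct: float
    product_uv: float        # amplitude * incidence / 100
    n_measurable: int
    n_detected: int


def records_to_frame(records: Sequence[ConnectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motoneuron_id": [r.motoneuron_id for r in records],
            "category": [r.category for r in records],
            "nerve": [r.nerve for r in records],
            "amplitude_uv": [r.amplitude_uv for r in records],
            "detected": [r.detected for r in records],
            "measurable": [r.measurable for r in records],
        }
    )


def motoneuron_table(
    records: Sequence[ConnectionRecord], group_by: str = "category"
) -> pd.DataFrame:
    """Per-resampling-unit table: columns ``group``, ``amp0``, ``detected``.

    The unit is the motoneuron. Grouping by category, a motoneuron with
    detected IPSPs from several nerves contributes the mean of those
    amplitudes once; grouping by nerve, each motoneuron-nerve record is a
    unit within its nerve's group (still one row per motoneuron per nerve).
    ``amp0`` is the zero-inclusive amplitude. Non-measurable records are
    dropped first.
    """
    if group_by not in ("category", "nerve"):
        raise ConfigurationError("group_by must be 'category' or 'nerve'")
    df = records_to_frame(records)
    df = df[df["measurable"]]
    if group_by == "nerve":
        det = df["detected"].to_numpy(bool)
        return pd.DataFrame(
            {
                "group": df["nerve"].to_numpy(),
                "motoneuron_id": df["motoneuron_id"].to_numpy(),
                "amp0": np.where(det, df["amplitude_uv"].to_numpy(float), 0.0),
                "detected": det,
            }
        )

    rows = []
    for (mn, cat), sub in df.groupby(["motoneuron_id", "category"], sort=False):
        det = sub[sub["detected"]]
        amp = float(det["amplitude_uv"].mean()) if len(det) else 0.0
        rows.append(
            {"group": cat, "motoneuron_id": mn, "amp0": amp, "detected": len(det) > 0}
        )
    return pd.DataFrame(rows)


def _measure_rows(amp0: np.ndarray, detected: np.ndarray, measure: Measure) -> float:
    n_det = detected.sum()
    if measure == "product":
        return float(amp0.mean())
    if measure == "incidence":
        return float(100.0 * detected.mean())
    if measure == "amplitude":
        return float(amp0.sum() / n_det) if n_det else 0.0
    raise ConfigurationError(f"unknown measure {measure!r}")


def population_measures(
    records: Sequence[ConnectionRecord], group_by: str = "category"
) -> dict[str, PopulationMeasure]:
    """Amplitude, incidence and their product per group."""
    table = motoneuron_table(records, group_by)
    out: dict[str, PopulationMeasure] = {}
    for group, sub in table.groupby("group", sort=False):
        amp0 = sub["amp0"].to_numpy(float)
        det = sub["detected"].to_numpy(bool)
        out[str(group)] = PopulationMeasure(
            amplitude_uv=_measure_rows(amp0, det, "amplitude"),
            incidence_pct=_measure_rows(amp0, det, "incidence"),
            product_uv=_measure_rows(amp0, det, "product"),
            n_measurable=int(len(sub)),
            n_detected=int(det.sum()),
        )
    return out


def _bootstrap_stats(
    amp0: np.ndarray, det: np.ndarray, measure: Measure, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(amp0)
    idx = rng.integers(0, n, size=(n_boot, n))
    a = amp0[idx]
    d = det[idx]
    if measure == "product":
        return a.mean(axis=1)
    if measure == "incidence":
        return 100.0 * d.mean(axis=1)
    n_det = d.sum(axis=1)
    with np.errstate(invalid="ignore"):
        vals = np.where(n_det > 0, a.sum(axis=1) / np.maximum(n_det, 1), 0.0)
    return vals


def bootstrap_ci(
    records: Sequence[ConnectionRecord],
    group_by: str = "category",
    measure: Measure = "product",
    n_boot: int = 10000,
    seed: int = 0,
    ci: float = 95.0,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CI per group, resampling motoneurons with replacement."""
    table = motoneuron_table(records, group_by)
    out: dict[str, tuple[float, float]] = {}
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    for group, sub in table.groupby("group", sort=False):
        rng = child_rng(seed, "bootstrap", str(group), measure)
        vals = _bootstrap_stats(
            sub["amp0"].to_numpy(float), sub["detected"].to_numpy(bool),
            measure, n_boot, rng,
        )
        lo, hi = np.percentile(vals, [lo_q, hi_q])
        out[str(group)] = (float(lo), float(hi))
    return out


def permutation_category_test(
    records: Sequence[ConnectionRecord],
    category: str,
    measure: Measure = "product",
    n_perm: int = 10000,
    seed: int = 0,
    group_by: str = "category",
) -> float:
    """Monte-Carlo comparison of one group against the full cohort.

    The null statistic is the measure computed on ``n_c`` units drawn without
    replacement from the whole cohort; the two-sided p-value doubles the
    smaller tail, with add-one smoothing so p is never exactly 0. Returns 1
    when the group is the whole cohort.
    """
    table = motoneuron_table(records, group_by)
    mask = (table["group"] == category).to_numpy()
    n_c = int(mask.sum())
    if n_c == 0:
        raise ConfigurationError(f"empty group {category!r}")
    amp0 = table["amp0"].to_numpy(float)
    det = table["detected"].to_numpy(bool)
    n = len(table)
    if n_c == n:
        return 1.0
    obs = _measure_rows(amp0[mask], det[mask], measure)
    rng = child_rng(seed, "permutation", category, measure)
    # vectorized subset draws: argpartition of uniform noise
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, n_c - 1, axis=1)[:, :n_c]
    a = amp0[idx]
    d = det[idx]
    if measure == "product":
        null = a.mean(axis=1)
    elif measure == "incidence":
        null = 100.0 * d.mean(axis=1)
    else:
        n_det = d.sum(axis=1)
        null = np.where(n_det > 0, a.sum(axis=1) / np.maximum(n_det, 1), 0.0)
    p_ge = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    p_le = (1.0 + np.sum(null <= obs)) / (n_perm + 1.0)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def binomial_proportion_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial test by tail doubling.

    The smaller of P(X <= k) and P(X >= k) under Binomial(n, p0) is doubled
    and capped at 1.
    """
    if not 0 <= k <= n:
        raise ConfigurationError("need 0 <= k <= n")
    if not 0 <= p0 <= 1:
        raise ConfigurationError("need 0 <= p0 <= 1")
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))


def benjamini_hochberg(pvals: Sequence[float] | np.ndarray, q: float = 0.05) -> np.ndarray:
    """Step-up FDR control: boolean acceptance flags, no adjusted p-values.

    Accepts (declares significant) every hypothesis with p <= p_(k) where k is
    the largest rank with p_(k) <= k*q/m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
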