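"""LBB colorimetric assay calibration and gated group-comparison statistics.

Leucoberbelin blue (LBB) turns blue in the presence of Mn above oxidation
state +II; absorbance at 620 nm is calibrated against KMnO4 standards and
results are expressed as Mn(IV) equivalents (uM on the permanganate scale).
Oxidation rates are normalized per ug protein per hour, and inhibitor /
substrate assays are normalized to a matrix control (percent of control).

Group comparisons follow a variance-gated workflow common in small-n assay
work: homogeneity of variances is tested first (Levene by default, Bartlett
optionally); homogeneous groups get one-way ANOVA with a Tukey-Kramer post
hoc, heterogeneous groups get Kruskal-Wallis with a Dunn-Bonferroni post
hoc; two-group comparisons use an independent-samples t test.  Post hoc
matrices are summarized as compact letter displays: two groups share a
letter iff they are not significantly different.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear absorbance = intercept + slope * concentration map."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int
    wavelength_nm: float = 620.0

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise ValueError("need at least 2 standards")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the gated multi-group comparison."""

    gate: str  # "homogeneous" | "heterogeneous"
    gate_test: str  # "levene" | "bartlett"
    gate_statistic: float
    gate_p: float
    omnibus: str  # "anova" | "kruskal-wallis"
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str  # "tukey-kramer" | "dunn-bonferroni"
    posthoc_p: pd.DataFrame  # symmetric matrix of adjusted p-values
    letters: Mapping[str, str]
    alpha: float = 0.05


def fit_standard_curve(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    r_squared_floor: float = 0.98,
) -> CalibrationCurve:
    """Fit the KMnO4 standard curve by ordinary least squares.

    Warns (does not fail) when r-squared falls below *r_squared_floor* —
    a poor curve usually means a pipetting or reagent problem worth a look,
    but the fit is still returned for inspection.
    """
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.shape != absb.shape or conc.ndim != 1:
        raise ValueError("concentrations and absorbances must be equal-length 1-D")
    if np.unique(conc).size < 2:
        raise ValueError("standards must span at least 2 distinct concentrations")
    fit = stats.linregress(conc, absb)
    r2 = float(fit.rvalue**2) if not np.isnan(fit.rvalue) else 1.0
    if r2 < r_squared_floor:
        warnings.warn(
            f"standard curve r^2 = {r2:.4f} below floor {r_squared_floor}",
            stacklevel=2,
        )
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_standards=int(conc.size),
    )


def absorbance_to_mnox(
    absorbance,
    curve: CalibrationCurve,
    dilution_factor: float = 1.0,
):
    """Invert the standard curve to Mn(IV)-equivalent concentration (uM).

    ``conc = dilution_factor * (A - intercept) / slope``.  Negative results
    (blank noise) are clamped to zero; returns ``(conc, clamped)`` where
    *clamped* flags the values that were below zero before clamping.
    """
    if curve.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {curve.slope}")
    a = np.asarray(absorbance, dtype=float)
    conc = dilution_factor * (a - curve.intercept) / curve.slope
    clamped = conc < 0
    conc = np.where(clamped, 0.0, conc)
    if np.isscalar(absorbance) or a.ndim == 0:
        return float(conc), bool(clamped)
    return conc, clamped


def oxidation_rate(mnox_uM, protein_mass_ug, hours):
    """Mn(II) oxidation rate in uM Mn(IV) equivalents per ug protein per hour."""
    mass = np.asarray(protein_mass_ug, dtype=float)
    t = np.asarray(hours, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("protein_mass_ug must be > 0")
    if np.any(t <= 0):
        raise ValueError("hours must be > 0")
    rate = np.asarray(mnox_uM, dtype=float) / (mass * t)
    return float(rate) if rate.ndim == 0 else rate


def normalize_to_control(treated, control):
    """Express values as percent of the matrix-control mean.

    The matrix control is the 0-uM inhibitor/substrate condition; its own
    values normalize to mean 100.
    """
    ctrl = np.asarray(control, dtype=float)
    mean = ctrl.mean()
    if not mean > 0:
        raise ValueError(f"control mean must be > 0, got {mean}")
    out = 100.0 * np.asarray(treated, dtype=float) / mean
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Gated comparisons


def _dunn_bonferroni(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with Bonferroni adjustment.

    Uses pooled ranks with the standard tie correction; each two-sided p is
    multiplied by the number of pairwise comparisons (capped at 1).
    """
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(values)
    n_total = values.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    k = len(labels)
    n_pairs = k * (k - 1) // 2
    p = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs)
        p.loc[a, b] = p.loc[b, a] = p_adj
    return p


def _tukey_kramer(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    labels = list(groups)
    res = stats.tukey_hsd(*(groups[g] for g in labels))
    p = pd.DataFrame(res.pvalue, index=labels, columns=labels)
    np.fill_diagonal(p.values, 1.0)
    return p


def compact_letter_display(
    posthoc_p: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Assign letters so two groups share a letter iff p >= alpha.

    Insert-and-absorb: start from one letter covering everything, split on
    each significant pair, absorb redundant letters.  The sharing relation
    of the result reproduces the non-significance relation exactly.
    """
    mat = posthoc_p
    if list(mat.index) != list(mat.columns):
        raise ValueError("post hoc matrix must have identical row/column labels")
    if not np.allclose(mat.values, mat.values.T, equal_nan=True):
        raise ValueError("post hoc matrix must be symmetric")
    labels = list(mat.index)
    letter_sets: list[set[str]] = [set(labels)]
    for a, b in itertools.combinations(labels, 2):
        if mat.loc[a, b] >= alpha:
            continue
        new_sets: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s
            and not any(
                s < t or (s == t and i > j) for j, t in enumerate(new_sets) if j != i
            )
        ]
    # stable letter order: by first group each set covers
    order = {g: i for i, g in enumerate(labels)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for i, s in enumerate(letter_sets):
        letter = alphabet[i % len(alphabet)] * (i // len(alphabet) + 1)
        for g in labels:
            if g in s:
                out[g] += letter
    return out


def gated_omnibus(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    gate_test: str = "levene",
) -> tuple[str, float, float, str, float, float]:
    """Variance gate + omnibus test only (no post hoc).

    Returns ``(gate, gate_statistic, gate_p, omnibus, statistic, p)``.
    The omnibus is one-way ANOVA iff the gate test retains homogeneity
    (``gate_p >= alpha``), Kruskal-Wallis otherwise.  This is the decision
    core of :func:`compare_groups`, exposed separately because calibration
    studies (e.g. type-I-error simulations) need it without the cost of the
    pairwise post hoc.
    """
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if gate_test == "levene":
        gstat, gp = stats.levene(*samples, center="median")
    else:
        gstat, gp = stats.bartlett(*samples)
    if gp >= alpha:
        stat, p = stats.f_oneway(*samples)
        return "homogeneous", float(gstat), float(gp), "anova", float(stat), float(p)
    stat, p = stats.kruskal(*samples)
    return (
        "heterogeneous",
        float(gstat),
        float(gp),
        "kruskal-wallis",
        float(stat),
        float(p),
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    gate_test: str = "levene",
) -> ComparisonResult:
    """Run the variance-gated multi-group comparison.

    If the gate test does not reject homogeneity of variances at *alpha*,
    the omnibus test is one-way ANOVA with a Tukey-Kramer post hoc;
    otherwise Kruskal-Wallis with Dunn-Bonferroni.  For exactly two groups
    use :func:`two_group_test`.
    """
    if gate_test not in ("levene", "bartlett"):
        raise ValueError("gate_test must be 'levene' or 'bartlett'")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    samples = list(arrays.values())

    if all(np.ptp(v) == 0 for v in arrays.values()) and (
        len({v[0] for v in arrays.values()}) == 1
    ):
        # all observations identical: every test is degenerate; report the
        # trivially non-significant outcome
        labels = list(arrays)
        p = pd.DataFrame(1.0, index=labels, columns=labels)
        return ComparisonResult(
            gate="homogeneous",
            gate_test=gate_test,
            gate_statistic=0.0,
            gate_p=1.0,
            omnibus="anova",
            omnibus_statistic=0.0,
            omnibus_p=1.0,
            posthoc_test="tukey-kramer",
            posthoc_p=p,
            letters=compact_letter_display(p, alpha),
            alpha=alpha,
        )

    gate, gstat, gp, omnibus, stat, p_omni = gated_omnibus(
        arrays, alpha, gate_test
    )
    if gate == "homogeneous":
        posthoc, posthoc_name = _tukey_kramer(arrays), "tukey-kramer"
    else:
        posthoc, posthoc_name = _dunn_bonferroni(arrays), "dunn-bonferroni"

    return ComparisonResult(
        gate=gate,
        gate_test=gate_test,
        gate_statistic=float(gstat),
        gate_p=float(gp),
        omnibus=omnibus,
        omnibus_statistic=float(stat),
        omnibus_p=float(p_omni),
        posthoc_test=posthoc_name,
        posthoc_p=posthoc,
        letters=compact_letter_display(posthoc, alpha),
        alpha=alpha,
    )


def two_group_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Independent-samples t test (Welch by default; pooled optional).

    Returns ``(statistic, p)``.  Two zero-variance groups with equal means
    yield ``(0.0, 1.0)`` by convention rather than a NaN.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        logger.info("both groups constant and equal; returning p = 1 by convention")
        return 0.0, 1.0
    stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(stat), float(p)
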