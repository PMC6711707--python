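"""Two-dimensional receptor–ligand adhesion kinetics.

The micropipette adhesion-frequency assay brings a receptor-bearing cell
and a ligand-coated cell (typically a red blood cell) into repeated
contact–retraction cycles and scores each cycle as adhesive or not.  With
both molecules anchored to apposed membranes, bond formation is a surface
(2D) reaction and the affinity carries area units.  Under the standard
probabilistic kinetic model the number of bonds at contact time ``tc`` is
Poisson with mean

    <n>(tc) = mr * ml * AcKa * (1 - exp(-koff * tc))

where ``mr`` and ``ml`` are the receptor and ligand surface densities
(μm⁻²), ``AcKa`` is the effective 2D binding affinity (μm⁴, contact area
times affinity — the two are never separable in this assay) and ``koff``
the off-rate (s⁻¹).  The probability of at least one bond, i.e. the
adhesion frequency, is

    Pa(tc) = 1 - exp(-<n>(tc))

and the effective 2D on-rate follows as ``Ackon = AcKa * koff``
(μm⁴ s⁻¹).

This module evaluates the model, fits (AcKa, koff) to adhesion-frequency
curves by binomially weighted nonlinear least squares (or maximum
likelihood), derives bootstrap standard errors over cell pairs, applies
the assay's affinity detection limit (1e-8 μm⁴ by default), and compares
fitted parameter sets between conditions on the log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DensityPair",
    "KineticParams",
    "AdhesionObservation",
    "AdhesionCurve",
    "KineticFit",
    "BootstrapErrors",
    "FitComparison",
    "DEFAULT_DETECTION_LIMIT",
    "mean_bond_number",
    "adhesion_probability",
    "fit_curve",
    "derive_on_rate",
    "bootstrap_errors",
    "fit_curve_with_errors",
    "detection_limit_check",
    "compare_fits",
    "curve_from_cycles",
    "curve_from_csv",
    "fit_to_json_record",
    "predicted_table",
]

#: Affinity below which the assay cannot distinguish binding from nothing (μm⁴).
DEFAULT_DETECTION_LIMIT = 1e-8

_LOG_KA_BOUNDS = (math.log(1e-13), math.log(1e-2))
_LOG_KOFF_BOUNDS = (math.log(1e-3), math.log(1e3))


@dataclass(frozen=True)
class DensityPair:
    """Receptor and ligand surface densities in molecules·μm⁻²."""

    mr: float
    ml: float

    def __post_init__(self) -> None:
        if not (self.mr > 0 and self.ml > 0):
            raise ValueError("surface densities must be positive")

    @property
    def product(self) -> float:
        return self.mr * self.ml


@dataclass(frozen=True)
class KineticParams:
    """Effective 2D kinetic parameters.

    Attributes
    ----------
    ac_ka : float
        Effective 2D binding affinity AcKa (μm⁴).
    koff : float
        Off-rate (s⁻¹).
    """

    ac_ka: float
    koff: float

    def __post_init__(self) -> None:
        if not (self.ac_ka > 0 and self.koff > 0):
            raise ValueError("AcKa and koff must be positive")

    @property
    def ac_kon(self) -> float:
        """Effective 2D on-rate Ackon = AcKa × koff (μm⁴ s⁻¹)."""
        return self.ac_ka * self.koff


@dataclass(frozen=True)
class AdhesionObservation:
    """Adhesion tally for one cell pair at one contact time."""

    cell_pair_id: str
    tc: float
    n_cycles: int
    n_adhesions: int

    def __post_init__(self) -> None:
        if self.tc <= 0:
            raise ValueError("contact time must be positive")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if not 0 <= self.n_adhesions <= self.n_cycles:
            raise ValueError("n_adhesions must lie in [0, n_cycles]")

    @property
    def pa(self) -> float:
        """Observed adhesion frequency for this cell pair."""
        return self.n_adhesions / self.n_cycles


@dataclass(frozen=True)
class AdhesionCurve:
    """A set of adhesion observations sharing one density record."""

    observations: tuple[AdhesionObservation, ...]
    densities: DensityPair
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))

    @property
    def contact_times(self) -> np.ndarray:
        return np.unique([o.tc for o in self.observations])

    def pooled(self) -> pd.DataFrame:
        """Pool cycles across cell pairs per contact time.

        Returns a frame with columns ``tc``, ``n_cycles``, ``n_adhesions``
        and ``pa`` (pooled adhesion frequency), sorted by ``tc``.
        """
        rows = pd.DataFrame(
            {
                "tc": [o.tc for o in self.observations],
                "n_cycles": [o.n_cycles for o in self.observations],
                "n_adhesions": [o.n_adhesions for o in self.observations],
            }
        )
        pooled = rows.groupby("tc", as_index=False).sum()
        pooled["pa"] = pooled["n_adhesions"] / pooled["n_cycles"]
        return pooled


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting the adhesion-frequency model to one curve.

    ``params`` is ``None`` when ``nd_flag`` is set (no adhesion above the
    detection limit — the printed outcome "ND"); such fits must not be
    compared numerically.
    """

    params: KineticParams | None
    converged: bool
    nd_flag: bool
    residuals: pd.DataFrame | None
    n_obs: int
    objective: float = math.nan
    method: str = "wls"
    se_ac_ka: float | None = None
    se_koff: float | None = None
    se_ac_kon: float | None = None
    seed: int | None = None

    def require_params(self) -> KineticParams:
        if self.nd_flag or self.params is None:
            raise ValueError(
                "fit is not-detectable (ND); use detection_limit_check before "
                "comparing parameters numerically"
            )
        return self.params


@dataclass(frozen=True)
class BootstrapErrors:
    """Bootstrap standard errors for (AcKa, koff, Ackon)."""

    se_ac_ka: float
    se_koff: float
    se_ac_kon: float
    n_boot: int
    n_converged: int


@dataclass(frozen=True)
class FitComparison:
    """Fold changes (a relative to b) and log-scale z tests."""

    fold_ac_ka: float
    fold_ac_kon: float
    fold_koff: float
    z_ac_ka: float
    p_ac_ka: float
    z_ac_kon: float
    p_ac_kon: float


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def mean_bond_number(
    tc: float | np.ndarray, densities: DensityPair, params: KineticParams
) -> float | np.ndarray:
    """Mean bond count <n>(tc) = mr·ml·AcKa·(1 − exp(−koff·tc)).

    Non-negative and monotone non-decreasing in ``tc``; saturates at
    ``mr·ml·AcKa`` as ``tc → ∞``.

    Raises
    ------
    ValueError
        If any contact time is negative.
    """
    tc_arr = np.asarray(tc, dtype=float)
    if np.any(tc_arr < 0):
        raise ValueError("contact time must be non-negative")
    out = densities.product * params.ac_ka * (-np.expm1(-params.koff * tc_arr))
    return float(out) if np.isscalar(tc) or tc_arr.ndim == 0 else out


def adhesion_probability(
    tc: float | np.ndarray, densities: DensityPair, params: KineticParams
) -> float | np.ndarray:
    """Adhesion frequency Pa(tc) = 1 − exp(−<n>(tc)).

    Lies in [0, 1); monotone non-decreasing in ``tc`` and in each of
    ``mr``, ``ml``, ``AcKa``; plateaus at ``1 − exp(−mr·ml·AcKa)``.
    """
    n_mean = mean_bond_number(tc, densities, params)
    out = -np.expm1(-np.asarray(n_mean, dtype=float))
    return float(out) if np.isscalar(n_mean) else out


def derive_on_rate(params: KineticParams) -> float:
    """Effective 2D on-rate Ackon = AcKa × koff (μm⁴ s⁻¹)."""
    return params.ac_kon


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pooled_arrays(curve: AdhesionCurve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pooled = curve.pooled()
    return (
        pooled["tc"].to_numpy(float),
        pooled["n_cycles"].to_numpy(float),
        pooled["n_adhesions"].to_numpy(float),
    )


def _model_pa(log_theta: np.ndarray, tc: np.ndarray, mrml: float) -> np.ndarray:
    ac_ka = math.exp(log_theta[0])
    koff = math.exp(log_theta[1])
    n_mean = mrml * ac_ka * (-np.expm1(-koff * tc))
    return -np.expm1(-n_mean)

def _wls_sigma(phat: np.ndarray, n: np.ndarray) -> np.ndarray:
    # Binomial variance p(1-p)/n with p(1-p) floored at 1/(4n) so that
    # all-success/all-failure contact times keep a finite weight.
    pq = np.maximum(phat * (1.0 - phat), 1.0 / (4.0 * n))
    return np.sqrt(pq / n)


def _start_grid(tc: np.ndarray, n: np.ndarray, k: np.ndarray, mrml: float) -> list[np.ndarray]:
    phat_max = float(np.max(k / n))
    phat_max = min(max(phat_max, 1.0 / (2.0 * float(np.max(n)))), 0.99)
    ka_plateau = -math.log1p(-phat_max) / mrml
    starts = []
    for ka_scale in (0.5, 1.0, 2.0):
        for koff0 in (0.1, 1.0, 10.0):
            log_ka = math.log(ka_plateau * ka_scale)
            log_ka = min(max(log_ka, _LOG_KA_BOUNDS[0]), _LOG_KA_BOUNDS[1])
            starts.append(np.array([log_ka, math.log(koff0)]))
    return starts


def fit_curve(
    curve: AdhesionCurve,
    init: KineticParams | None = None,
    seed: int = 0,
    method: str = "wls",
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> KineticFit:
    """Fit (AcKa, koff) to an adhesion-frequency curve.

    Cycles are pooled per contact time; the default objective is weighted
    least squares on pooled adhesion frequencies with binomial variance
    weights, minimized over (log AcKa, log koff) to enforce positivity.
    ``method="mle"`` maximizes the binomial likelihood instead; on clean
    data the two agree within their standard errors.

    Optimization is multi-start from a deterministic grid (AcKa seeded by
    plateau inversion, koff ∈ {0.1, 1, 10} s⁻¹), so results do not depend
    on ``seed``; the argument is accepted for interface stability and is
    echoed into the fit record.

    Parameters
    ----------
    curve : AdhesionCurve
        Observations (≥2 distinct contact times) plus densities.
    init : KineticParams, optional
        Extra starting point added to the grid.
    method : {"wls", "mle"}
    detection_limit : float
        Affinity floor (μm⁴) used only to annotate all-zero curves.

    Returns
    -------
    KineticFit
        With ``nd_flag`` set (and no parameters) when no cycle adhered.
    """
    if method not in ("wls", "mle"):
        raise ValueError(f"unknown fitting method: {method!r}")
    tc, n, k = _pooled_arrays(curve)
    if len(tc) < 2:
        raise ValueError("need at least 2 distinct contact times to fit")
    n_obs = len(curve.observations)
    if float(k.sum()) == 0.0:
        # Detection-limit path: nothing ever adhered.
        return KineticFit(
            params=None, converged=True, nd_flag=True, residuals=None,
            n_obs=n_obs, method=method, seed=seed,
        )

    mrml = curve.densities.product
    phat = k / n
    starts = _start_grid(tc, n, k, mrml)
    if init is not None:
        starts.append(np.array([math.log(init.ac_ka), math.log(init.koff)]))

    bounds_lo = np.array([_LOG_KA_BOUNDS[0], _LOG_KOFF_BOUNDS[0]])
    bounds_hi = np.array([_LOG_KA_BOUNDS[1], _LOG_KOFF_BOUNDS[1]])

    best: tuple[float, np.ndarray, bool] | None = None
    if method == "wls":
        sigma = _wls_sigma(phat, n)

        def resid(log_theta: np.ndarray) -> np.ndarray:
            return (phat - _model_pa(log_theta, tc, mrml)) / sigma

        for x0 in starts:
            res = optimize.least_squares(
                resid, x0, bounds=(bounds_lo, bounds_hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            cost = float(res.cost)
            if best is None or cost < best[0]:
                best = (cost, res.x, bool(res.success))
    else:
        eps = 1e-12

        def nll(log_theta: np.ndarray) -> float:
            pa = np.clip(_model_pa(log_theta, tc, mrml), eps, 1.0 - eps)
            return -float(np.sum(k * np.log(pa) + (n - k) * np.log1p(-pa)))

        for x0 in starts:
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B",
                bounds=list(zip(bounds_lo, bounds_hi)),
                options={"ftol": 1e-14, "gtol": 1e-12},
            )
            cost = float(res.fun)
            if best is None or cost < best[0]:
                best = (cost, res.x, bool(res.success))

    assert best is not None
    cost, x_opt, success = best
    params = KineticParams(ac_ka=math.exp(x_opt[0]), koff=math.exp(x_opt[1]))
    predicted = _model_pa(x_opt, tc, mrml)
    residuals = pd.DataFrame(
        {"tc": tc, "n_cycles": n.astype(int), "observed_pa": phat,
         "predicted_pa": predicted, "residual": phat - predicted}
    )
    return KineticFit(
        params=params, converged=success, nd_flag=False, residuals=residuals,
        n_obs=n_obs, objective=cost, method=method, seed=seed,
    )


def bootstrap_errors(
    curve: AdhesionCurve,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "wls",
) -> BootstrapErrors:
    """Bootstrap SEs for (AcKa, koff, Ackon) over cell pairs.

    The cell pair is the assay's replication unit, so pairs are resampled
    with replacement *within each contact time* and the curve refit per
    resample; the SE is the standard deviation of the estimates across
    converged refits.  Fully reproducible given ``seed``.

    Raises
    ------
    RuntimeError
        If more than half the bootstrap refits fail to converge.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for stable SEs")
    # Fit once up-front so an unfittable curve raises before resampling.
    fit_curve(curve, method=method).require_params()
    rng = np.random.default_rng(seed)
    by_tc: dict[float, list[AdhesionObservation]] = {}
    for obs in curve.observations:
        by_tc.setdefault(obs.tc, []).append(obs)

    estimates = []
    n_failed = 0
    for _ in range(n_boot):
        resampled: list[AdhesionObservation] = []
        for tc_val, group in by_tc.items():
            idx = rng.integers(0, len(group), size=len(group))
            resampled.extend(group[i] for i in idx)
        boot_curve = AdhesionCurve(tuple(resampled), curve.densities, curve.label)
        try:
            fit = fit_curve(boot_curve, method=method)
            p = fit.require_params()
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        estimates.append((p.ac_ka, p.koff, p.ac_kon))

    if n_failed > n_boot // 2:
        raise RuntimeError(
            f"bootstrap unstable: {n_failed}/{n_boot} refits failed or "
            "did not converge"
        )
    arr = np.array(estimates)
    sds = arr.std(axis=0, ddof=1)
    return BootstrapErrors(
        se_ac_ka=float(sds[0]), se_koff=float(sds[1]), se_ac_kon=float(sds[2]),
        n_boot=n_boot, n_converged=len(estimates),
    )


def fit_curve_with_errors(
    curve: AdhesionCurve,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "wls",
) -> KineticFit:
    """Convenience: :func:`fit_curve` plus bootstrap SEs attached."""
    fit = fit_curve(curve, seed=seed, method=method)
    if fit.nd_flag:
        return fit
    bse = bootstrap_errors(curve, n_boot=n_boot, seed=seed, method=method)
    return replace(
        fit, se_ac_ka=bse.se_ac_ka, se_koff=bse.se_koff, se_ac_kon=bse.se_ac_kon
    )


def detection_limit_check(
    fit: KineticFit, limit: float = DEFAULT_DETECTION_LIMIT
) -> bool:
    """True when the fit should be reported as not-detectable (ND).

    A fit is ND when nothing adhered or the fitted affinity falls below
    the assay's detection limit (default 1e-8 μm⁴).
    """
    if fit.nd_flag:
        return True
    assert fit.params is not None
    return fit.params.ac_ka < limit


def compare_fits(a: KineticFit, b: KineticFit) -> FitComparison:
    """Fold changes of a over b with normal-approximation p-values.

    Fold changes are simple parameter ratios.  When both fits carry
    bootstrap SEs, a two-sided z test is performed on the log parameters
    (delta-method SE on the log scale, se_log ≈ se/estimate); otherwise
    the z and p entries are NaN.

    Raises
    ------
    ValueError
        If either fit is ND — consult :func:`detection_limit_check` first.
    """
    pa, pb = a.require_params(), b.require_params()
    fold_ka = pa.ac_ka / pb.ac_ka
    fold_kon = pa.ac_kon / pb.ac_kon
    fold_koff = pa.koff / pb.koff

    def _ztest(va: float, vb: float, sa: float | None, sb: float | None):
        if sa is None or sb is None or sa < 0 or sb < 0:
            return math.nan, math.nan
        var_log = (sa / va) ** 2 + (sb / vb) ** 2
        if var_log == 0.0:
            return 0.0, 1.0
        z = (math.log(va) - math.log(vb)) / math.sqrt(var_log)
        return z, float(2.0 * stats.norm.sf(abs(z)))

    z_ka, p_ka = _ztest(pa.ac_ka, pb.ac_ka, a.se_ac_ka, b.se_ac_ka)
    z_kon, p_kon = _ztest(pa.ac_kon, pb.ac_kon, a.se_ac_kon, b.se_ac_kon)
    return FitComparison(
        fold_ac_ka=fold_ka, fold_ac_kon=fold_kon, fold_koff=fold_koff,
        z_ac_ka=z_ka, p_ac_ka=p_ka, z_ac_kon=z_kon, p_ac_kon=p_kon,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def curve_from_cycles(
    cycles: pd.DataFrame, densities: DensityPair, label: str = ""
) -> AdhesionCurve:
    """Build a curve from a cycle-level table.

    Expects columns ``cell_pair_id``, ``tc_s``, ``cycle_index`` and
    ``adhesion`` (0/1), one row per contact–retraction cycle.
    """
    required = {"cell_pair_id", "tc_s", "cycle_index", "adhesion"}
    missing = required - set(cycles.columns)
    if missing:
        raise ValueError(f"cycle table missing columns: {sorted(missing)}")
    if not cycles["adhesion"].isin([0, 1]).all():
        raise ValueError("adhesion column must be 0/1")
    grouped = cycles.groupby(["cell_pair_id", "tc_s"], as_index=False).agg(
        n_cycles=("adhesion", "size"), n_adhesions=("adhesion", "sum")
    )
    observations = tuple(
        AdhesionObservation(
            cell_pair_id=str(row.cell_pair_id), tc=float(row.tc_s),
            n_cycles=int(row.n_cycles), n_adhesions=int(row.n_adhesions),
        )
        for row in grouped.itertuples()
    )
    return AdhesionCurve(observations, densities, label)


def curve_from_csv(
    path, mr: float, ml: float, label: str = ""
) -> AdhesionCurve:
    """Read a cycle-level CSV (cell_pair_id, tc_s, cycle_index, adhesion)."""
    return curve_from_cycles(pd.read_csv(path), DensityPair(mr, ml), label)


def fit_to_json_record(fit: KineticFit) -> dict:
    """Flatten a fit into the JSON-friendly record written by pipelines."""
    record = {
        "converged": fit.converged,
        "nd": fit.nd_flag,
        "n_obs": fit.n_obs,
        "method": fit.method,
        "seed": fit.seed,
    }
    if fit.nd_flag or fit.params is None:
        record.update({"AcKa": None, "koff": None, "Ackon": None})
    else:
        record.update(
            {
                "AcKa": fit.params.ac_ka,
                "koff": fit.params.koff,
                "Ackon": fit.params.ac_kon,
                "se_AcKa": fit.se_ac_ka,
                "se_koff": fit.se_koff,
                "se_Ackon": fit.se_ac_kon,
            }
        )
    return record


def predicted_table(fit: KineticFit) -> pd.DataFrame:
    """Observed vs fitted Pa per contact time (copy of fit residual table)."""
    if fit.residuals is None:
        raise ValueError("ND fit has no residual table")
    return fit.residuals.copy()
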