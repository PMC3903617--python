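"""SPR kinetics and binding thermodynamics.

Langmuir 1:1 sensorgram fitting, K_D from rate constants, van't Hoff and
Eyring temperature analyses, and delta-vs-reference energetics.

Sign conventions (binding direction, 1 M standard state):

    dG0 = R*T*ln K_D = dH0 - T*dS0            (negative for tight binders)
    ln K_D        =  dH0/(R*T) - dS0/R        (van't Hoff)
    ln(kon*h/(kB*T)) = -dHa/(R*T) + dSa/R     (Eyring)

so the van't Hoff slope of ln K_D on 1/T is dH0/R and the Eyring slope of
ln(kon*h/(kB*T)) on 1/T is -dHa/R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import KB_OVER_H, R_KCAL, T_REF


@dataclass(frozen=True)
class KineticRecord:
    """One (variant, temperature) kinetic observation."""

    variant: str
    temperature: float  # K
    k_on: float         # M^-1 s^-1
    k_off: float        # s^-1
    k_d: float | None = None  # M, as supplied (printed); None -> derive
    nacl_mm: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")

    @property
    def k_d_from_rates(self) -> float:
        return self.k_off / self.k_on

    def kd_consistent(self, tol: float = 0.05) -> bool:
        """Does the supplied K_D agree with k_off/k_on within ``tol``?"""
        if self.k_d is None:
            return True
        return abs(self.k_d * self.k_on - self.k_off) / self.k_off <= tol


@dataclass
class Sensorgram:
    """One SPR trace: analyte concentration, time series, phase boundary."""

    concentration: float          # M
    time: np.ndarray              # s, strictly increasing
    response: np.ndarray          # RU
    t_assoc_end: float            # s; dissociation starts here

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(self.time) != len(self.response):
            raise ValueError("time/response length mismatch")


@dataclass
class LinearFitDiagnostics:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float


@dataclass
class ThermoParams:
    """Equilibrium van't Hoff parameters: dH0 kcal/mol, dS0 kcal/(mol K)."""

    dh: float
    ds: float
    diagnostics: LinearFitDiagnostics | None = None

    def dg(self, temperature: float = T_REF) -> float:
        return self.dh - temperature * self.ds

    def minus_t_ds(self, temperature: float = T_REF) -> float:
        return -temperature * self.ds


@dataclass
class ActivationParams:
    """Eyring activation parameters: dHa kcal/mol, dSa kcal/(mol K)."""

    dh: float
    ds: float
    diagnostics: LinearFitDiagnostics | None = None

    def dg(self, temperature: float = T_REF) -> float:
        return self.dh - temperature * self.ds

    def minus_t_ds(self, temperature: float = T_REF) -> float:
        return -temperature * self.ds


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Dissociation constant K_D = k_off / k_on, mol/L."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    return k_off / k_on


def gibbs_from_kd(k_d: float, temperature: float = T_REF) -> float:
    """Standard binding free energy dG0 = R*T*ln K_D, kcal/mol (1 M state)."""
    if k_d <= 0 or temperature <= 0:
        raise ValueError("K_D and temperature must be positive")
    return R_KCAL * temperature * math.log(k_d)


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFitDiagnostics:
    res = stats.linregress(x, y)
    n = len(x)
    # SE of intercept from linregress
    sx2 = np.sum((x - x.mean()) ** 2)
    intercept_se = res.stderr * math.sqrt(np.sum(x ** 2) / n) if sx2 > 0 else math.nan
    return LinearFitDiagnostics(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_se=float(res.stderr), intercept_se=float(intercept_se),
        r_squared=float(res.rvalue ** 2),
    )


def vant_hoff_fit(records: list[KineticRecord]) -> ThermoParams:
    """OLS of ln K_D on 1/T: slope = dH0/R, intercept = -dS0/R.

    K_D is taken from the supplied value when present, otherwise derived
    from the rates.  Requires >= 3 distinct temperatures.
    """
    if len(records) < 3:
        raise ValueError("van't Hoff fit needs >= 3 temperatures")
    t = np.array([r.temperature for r in records])
    if np.ptp(t) <= 0:
        raise ValueError("zero temperature spread")
    kd = np.array([r.k_d if r.k_d is not None else r.k_d_from_rates
                   for r in records])
    diag = _ols(1.0 / t, np.log(kd))
    return ThermoParams(dh=diag.slope * R_KCAL, ds=-diag.intercept * R_KCAL,
                        diagnostics=diag)


def eyring_fit(records: list[KineticRecord]) -> ActivationParams:
    """OLS of ln(kon*h/(kB*T)) on 1/T: slope = -dHa/R, intercept = dSa/R."""
    if len(records) < 3:
        raise ValueError("Eyring fit needs >= 3 temperatures")
    t = np.array([r.temperature for r in records])
    if np.ptp(t) <= 0:
        raise ValueError("zero temperature spread")
    kon = np.array([r.k_on for r in records])
    y = np.log(kon / (KB_OVER_H * t))
    diag = _ols(1.0 / t, y)
    return ActivationParams(dh=-diag.slope * R_KCAL, ds=diag.intercept * R_KCAL,
                            diagnostics=diag)


# --------------------------------------------------------------------------
# Langmuir 1:1 sensorgram fitting
# --------------------------------------------------------------------------

def _model_response(sg: Sensorgram, k_on: float, k_off: float, r_max: float):
    c = sg.concentration
    k_obs = k_on * c + k_off
    r_eq = r_max * c / (c + k_off / k_on) if c > 0 else 0.0
    t = sg.time
    assoc = t <= sg.t_assoc_end
    resp = np.empty_like(t)
    resp[assoc] = r_eq * (1.0 - np.exp(-k_obs * t[assoc]))
    r_end = r_eq * (1.0 - math.exp(-k_obs * sg.t_assoc_end))
    resp[~assoc] = r_end * np.exp(-k_off * (t[~assoc] - sg.t_assoc_end))
    return resp


@dataclass
class SensorgramFit:
    k_on: float
    k_off: float
    r_max: float
    k_on_se: float
    k_off_se: float
    residual_rms: float
    n_points: int

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on


def fit_sensorgram(sensorgrams: list[Sensorgram],
                   initial: tuple[float, float, float] | None = None) -> SensorgramFit:
    """Global Langmuir 1:1 least-squares fit across concentrations.

    Shared (k_on, k_off, R_max) are fitted jointly to all traces.
    Parameters are optimized in log space to enforce positivity.
    """
    if len(sensorgrams) < 2:
        raise ValueError("global fit needs >= 2 concentrations")
    if all(np.allclose(sg.response, 0) for sg in sensorgrams):
        raise ValueError("all-zero responses: nothing to fit")

    if initial is None:
        r0 = max(float(np.max(np.abs(sg.response))) for sg in sensorgrams)
        cmid = np.median([sg.concentration for sg in sensorgrams if sg.concentration > 0])
        initial = (1.0 / (cmid * 100.0), 1e-3, max(r0, 1.0))
    x0 = np.log(np.asarray(initial))

    def residuals(x):
        k_on, k_off, r_max = np.exp(x)
        out = []
        for sg in sensorgrams:
            out.append(_model_response(sg, k_on, k_off, r_max) - sg.response)
        return np.concatenate(out)

    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"sensorgram fit did not converge: {sol.message}; "
                           f"last iterate {np.exp(sol.x)}")
    k_on, k_off, r_max = np.exp(sol.x)
    res = sol.fun
    n = len(res)
    dof = max(n - 3, 1)
    s2 = float(res @ res) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        # delta method back to linear scale
        k_on_se = math.sqrt(cov[0, 0]) * k_on
        k_off_se = math.sqrt(cov[1, 1]) * k_off
    except np.linalg.LinAlgError:
        k_on_se = k_off_se = math.nan
    return SensorgramFit(float(k_on), float(k_off), float(r_max),
                         k_on_se, k_off_se, math.sqrt(s2), n)


# --------------------------------------------------------------------------
# Delta tables and compensation
# --------------------------------------------------------------------------

def delta_table(params: dict[str, ThermoParams | ActivationParams],
                reference: str,
                temperature: float = T_REF,
                kd: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-variant differences vs the reference (mutein - reference).

    Columns: dH, mTdS, dG and their dd-analogues at the given temperature;
    with ``kd`` also fold-change K_D_ref/K_D_mut and the improved flag.
    The identity ddG = ddH + (-T ddS) holds exactly by construction.
    """
    if reference not in params:
        raise KeyError(f"reference variant {reference!r} missing")
    ref = params[reference]
    rows = []
    for name, p in params.items():
        row = {
            "variant": name,
            "dH": p.dh,
            "mTdS": p.minus_t_ds(temperature),
            "dG": p.dg(temperature),
            "ddH": p.dh - ref.dh,
            "mTddS": p.minus_t_ds(temperature) - ref.minus_t_ds(temperature),
            "ddG": p.dg(temperature) - ref.dg(temperature),
        }
        if kd is not None and name in kd and reference in kd:
            row["fold_change"] = kd[reference] / kd[name]
            row["improved"] = row["fold_change"] > 1.0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("variant")
    return df


@dataclass
class CompensationSummary:
    slope: float
    intercept: float
    r_squared: float
    efficiency: dict[str, float] = field(default_factory=dict)


def compensation_summary(deltas: pd.DataFrame,
                         reference: str | None = None) -> CompensationSummary:
    """Enthalpy/entropy compensation: OLS of -T*ddS on ddH over muteins.

    ``efficiency`` is ddG/ddH per variant (the fraction of the enthalpy
    gain converted into free energy).  Requires >= 2 non-reference
    variants with nonzero ddH.
    """
    df = deltas
    if reference is not None and reference in df.index:
        df = df.drop(index=reference)
    df = df[df["ddH"] != 0]
    if len(df) < 2:
        raise ValueError("compensation summary needs >= 2 non-reference variants")
    x = df["ddH"].to_numpy()
    y = df["mTddS"].to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("degenerate (all-equal) ddH inputs")
    diag = _ols(x, y)
    eff = {name: float(row["ddG"] / row["ddH"]) for name, row in df.iterrows()}
    return CompensationSummary(diag.slope, diag.intercept, diag.r_squared, eff)


# --------------------------------------------------------------------------
# Kinetic tables (Table-1-style analysis)
# --------------------------------------------------------------------------

def read_kinetic_table(path) -> list[KineticRecord]:
    """Read a delimited rate table: variant, T_K, kon, koff[, KD_nM, NaCl]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        kd = None
        for col in ("KD_printed_nM", "KD_nM"):
            if col in df.columns and not pd.isna(row[col]):
                kd = float(row[col]) * 1e-9
        records.append(KineticRecord(
            variant=str(row["variant"]),
            temperature=float(row.get("T_K", T_REF)),
            k_on=float(row["kon"]),
            k_off=float(row["koff"]),
            k_d=kd,
            nacl_mm=float(row["NaCl_mM"]) if "NaCl_mM" in df.columns
            and not pd.isna(row.get("NaCl_mM")) else None,
        ))
    return records


def kinetic_summary(records: list[KineticRecord], reference: str = "WT",
                    kd_tolerance: float = 0.05) -> pd.DataFrame:
    """Recompute K_D from rates, fold-changes vs reference, improved flags.

    A row whose supplied K_D disagrees with k_off/k_on beyond
    ``kd_tolerance`` (relative) is flagged inconsistent, never silently
    corrected.
    """
    by_variant = {r.variant: r for r in records}
    if reference not in by_variant:
        raise KeyError(f"reference variant {reference!r} missing")
    kd_ref = by_variant[reference].k_d_from_rates
    kd_ref_printed = by_variant[reference].k_d
    rows = []
    for r in records:
        kd = r.k_d_from_rates
        rows.append({
            "variant": r.variant,
            "kon": r.k_on,
            "koff": r.k_off,
            "KD_nM": kd * 1e9,
            "KD_nM_2sf": float(f"{kd * 1e9:.2g}"),  # display rounding
            "KD_printed_nM": r.k_d * 1e9 if r.k_d is not None else math.nan,
            "fold_change": kd_ref / kd,
            "fold_change_printed": (kd_ref_printed / r.k_d
                                    if kd_ref_printed and r.k_d else math.nan),
            "improved": kd_ref / kd > 1.0,
            "kd_consistent": r.kd_consistent(kd_tolerance),
            "dG_kcal_mol": gibbs_from_kd(kd, r.temperature),
        })
    return pd.DataFrame(rows).set_index("variant")
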