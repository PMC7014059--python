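"""Infiltration analysis of the implant interfacial zone.

*Infiltration* is the mass (mg, per unit out-of-plane depth) of
fibrinogen or of blood plasma inside the interfacial zone at a sample
time; the *infiltration rate* is that mass divided by the total mass of
the same component in the whole fluid zone, in percent.  The 3 s run is
split into early [0, 1) s, mid [1, 2) s and late [2, 3] s stages; each
stage is summarised by its time-averaged infiltration (numerically equal
to the time integral over a 1 s stage, in mg.s), and stage values are
expressed as ratios to the superhydrophilic 5-degree reference surface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import StructuredMesh, Zone
from .properties import FluidProperties


class Species(str, enum.Enum):
    FIBRINOGEN = "fibrinogen"
    PLASMA = "plasma"


STAGES = (("early", 0.0, 1.0), ("mid", 1.0, 2.0), ("late", 2.0, 3.0))

SERIES_COLUMNS = ("t", "m_fib_interfacial_mg", "m_fib_total_mg",
                  "m_plasma_interfacial_mg", "m_plasma_total_mg",
                  "rate_fib_pct", "rate_plasma_pct")


# --------------------------------------------------------------------------
# per-state masses
# --------------------------------------------------------------------------

def _cell_masses(state, mesh: StructuredMesh, props: FluidProperties):
    """Fibrinogen and plasma mass per cell (kg): the plasma phase carries
    ``alpha_p * rho_m`` of mixture per unit volume, split ``Y0`` to
    fibrinogen and ``1 - Y0`` to plasma."""
    rho_m = props.mixture_density(state.Y0)
    vol = mesh.cell_area * mesh.depth
    phase = state.alpha_p * rho_m * vol
    return phase * state.Y0, phase * (1.0 - state.Y0)


def interfacial_mass(state, mesh: StructuredMesh, species: Species | str,
                     props: FluidProperties | None = None) -> float:
    """Mass (mg) of one component in the interfacial zone."""
    props = props or FluidProperties()
    fib, plas = _cell_masses(state, mesh, props)
    m = fib if Species(species) is Species.FIBRINOGEN else plas
    return 1e6 * float(m[mesh.zone == Zone.INTERFACIAL].sum())


def total_mass(state, mesh: StructuredMesh, species: Species | str,
               props: FluidProperties | None = None) -> float:
    """Mass (mg) of one component in the whole fluid zone."""
    props = props or FluidProperties()
    fib, plas = _cell_masses(state, mesh, props)
    m = fib if Species(species) is Species.FIBRINOGEN else plas
    return 1e6 * float(m[mesh.is_fluid].sum())


def infiltration_rate(state, mesh: StructuredMesh, species: Species | str,
                      props: FluidProperties | None = None) -> float:
    """100 x interfacial / total mass; NaN when the component is absent
    from the fluid zone (0/0 samples are flagged, not zeroed)."""
    props = props or FluidProperties()
    tot = total_mass(state, mesh, species, props)
    if tot <= 0.0:
        return float("nan")
    return 100.0 * interfacial_mass(state, mesh, species, props) / tot


def sample_infiltration(state, mesh: StructuredMesh,
                        props: FluidProperties | None = None) -> dict:
    """One time-series sample of all infiltration quantities."""
    props = props or FluidProperties()
    fib, plas = _cell_masses(state, mesh, props)
    inter = mesh.zone == Zone.INTERFACIAL
    fi = 1e6 * float(fib[inter].sum())
    ft = 1e6 * float(fib[mesh.is_fluid].sum())
    pi = 1e6 * float(plas[inter].sum())
    pt = 1e6 * float(plas[mesh.is_fluid].sum())
    return {
        "t": state.time,
        "m_fib_interfacial_mg": fi,
        "m_fib_total_mg": ft,
        "m_plasma_interfacial_mg": pi,
        "m_plasma_total_mg": pt,
        "rate_fib_pct": 100.0 * fi / ft if ft > 0 else float("nan"),
        "rate_plasma_pct": 100.0 * pi / pt if pt > 0 else float("nan"),
    }


def build_series(samples: list[dict]) -> pd.DataFrame:
    """Assemble samples into an infiltration time-series frame."""
    df = pd.DataFrame(samples, columns=list(SERIES_COLUMNS))
    t = df["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    return df


# --------------------------------------------------------------------------
# stage summaries and ratios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSummary:
    stage: str                 # "early" | "mid" | "late"
    fib_stage_value: float     # time-averaged fibrinogen infiltration, mg
    plasma_stage_value: float  # time-averaged plasma infiltration, mg
    complete: bool = True      # stage fully covered by the series


def _stage_average(t: np.ndarray, y: np.ndarray, t0: float, t1: float):
    """Trapezoidal time average of y over [t0, t1] using the available
    samples (sample points interpolated onto the stage boundaries)."""
    lo, hi = max(t0, t[0]), min(t1, t[-1])
    if hi <= lo:
        return float("nan"), False
    tt = np.unique(np.concatenate([[lo], t[(t > lo) & (t < hi)], [hi]]))
    yy = np.interp(tt, t, y)
    avg = float(np.trapezoid(yy, tt) / (hi - lo))
    return avg, bool(abs(lo - t0) < 1e-12 and abs(hi - t1) < 1e-12)


def stage_summary(series: pd.DataFrame) -> list[StageSummary]:
    """Per-stage time averages of both infiltration masses (mg).

    The three stage averages of a full 3 s run average exactly to the
    whole-run mean (shared trapezoid boundaries).  Stages not fully
    covered by the series are flagged ``complete=False``.
    """
    t = series["t"].to_numpy()
    fib = series["m_fib_interfacial_mg"].to_numpy()
    plas = series["m_plasma_interfacial_mg"].to_numpy()
    out = []
    for name, t0, t1 in STAGES:
        f, ok_f = _stage_average(t, fib, t0, t1)
        p, ok_p = _stage_average(t, plas, t0, t1)
        out.append(StageSummary(name, f, p, ok_f and ok_p))
    return out


def run_mean(series: pd.DataFrame, column: str) -> float:
    """Trapezoidal time average of one series column over the whole run;
    NaN samples (e.g. the undefined 0/0 rate at t = 0) are excluded."""
    t = series["t"].to_numpy()
    y = series[column].to_numpy()
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 2:
        return float(y[0]) if len(t) else float("nan")
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def ratio_table(summaries: dict[float, list[StageSummary]],
                reference: float = 5.0) -> pd.DataFrame:
    """Stage values of every contact-angle run as ratios to the reference
    (5-degree) run, rounded to 2 decimals; the reference column is 1.00
    by construction."""
    if reference not in summaries:
        raise ValueError(f"reference contact angle {reference} deg missing from summaries")
    ref = {s.stage: s for s in summaries[reference]}
    rows = []
    for angle, stages in sorted(summaries.items()):
        for s in stages:
            r = ref[s.stage]
            rows.append({
                "contact_angle_deg": angle,
                "stage": s.stage,
                "fib_stage_mg": s.fib_stage_value,
                "fib_ratio": round(s.fib_stage_value / r.fib_stage_value, 2),
                "plasma_stage_mg": s.plasma_stage_value,
                "plasma_ratio": round(s.plasma_stage_value / r.plasma_stage_value, 2),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# correlation of the two infiltration rates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    R: float
    p_value: float
    n: int
    slope: float
    intercept: float


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson R between two rate series, with the two-sided p-value from
    the t statistic (n - 2 degrees of freedom) and the regression line
    for scatter plots.  NaN samples are dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rate series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 finite samples")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return CorrelationResult(R=float(res.statistic), p_value=float(res.pvalue),
                             n=len(x), slope=float(reg.slope),
                             intercept=float(reg.intercept))


def rate_correlation(series: pd.DataFrame) -> CorrelationResult:
    """Correlation between the fibrinogen and plasma infiltration rates."""
    return pearson_correlation(series["rate_fib_pct"], series["rate_plasma_pct"])
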