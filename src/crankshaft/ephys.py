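"""Activation-curve fitting, kinetics, mutant-cycle energetics and statistics.

Whole-cell tail-current amplitudes I(V) are fit per cell with a
three-parameter Boltzmann

    I(V) = A / (1 + exp((V - V1/2) / k))

where V1/2 is the half-activation voltage (stored signed — negative for
hyperpolarization-activated channels) and k the inverse slope factor
(-RT/zF, mV). Per-cell fits are averaged (mean ± SEM), matching the
convention of fitting each cell first and averaging the parameters.

Activation/deactivation kinetics use a single exponential
I(t) = I0·exp(-t/τ). The apparent gating free energy is
ΔGapp = (RT/k)·V1/2 (kcal/mol; R = 1.987e-3 kcal/(mol·K), V1/2 and k in
the same voltage units so their ratio is dimensionless), and the
double-mutant-cycle non-additivity is

    ΔΔG = ΔGapp(wt) + ΔGapp(double) − ΔGapp(single1) − ΔGapp(single2).

|ΔΔG| beyond a threshold (default 1 kcal/mol) flags the two mutated
sites as energetically coupled. Group comparisons use one-way ANOVA
followed by Fisher's LSD (only when the ANOVA is significant at
α = 0.05), or Student's t-test for two groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "VoltageProtocol",
    "HCN1_PROTOCOL",
    "HCN2_PROTOCOL",
    "HCN4_PROTOCOL",
    "ActivationDataset",
    "BoltzmannFit",
    "KineticsFit",
    "ConstructEnergetics",
    "MutantCycle",
    "FitError",
    "SaturatedDataWarning",
    "boltzmann",
    "fit_boltzmann",
    "mean_activation",
    "fit_exponential",
    "delta_g_app",
    "construct_energetics",
    "mutant_cycle",
    "compare_groups",
    "camp_shift",
]

R_KCAL = 1.987e-3           # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.0  # K, room temperature (~25 °C)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


class SaturatedDataWarning(UserWarning):
    """Activation data show no inflection in the sampled voltage range."""


@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol for channel activation recordings (mV, s)."""

    holding_mV: float
    step_start_mV: float
    step_end_mV: float
    step_interval_mV: float
    step_duration_s: float
    tail_mV: float
    tail_duration_s: float

    def __post_init__(self) -> None:
        if self.step_duration_s <= 0 or self.tail_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.step_interval_mV == 0:
            raise ValueError("step interval must be nonzero")
        if (self.step_end_mV - self.step_start_mV) * self.step_interval_mV < 0:
            raise ValueError("step interval sign must run start -> end")

    @property
    def voltages(self) -> np.ndarray:
        """The arithmetic sequence of step voltages, start to end inclusive."""
        n = int(round((self.step_end_mV - self.step_start_mV)
                      / self.step_interval_mV)) + 1
        return self.step_start_mV + self.step_interval_mV * np.arange(n)


# Whole-cell protocols for the three isoforms (holding −30 mV, tails at −40 mV)
HCN1_PROTOCOL = VoltageProtocol(-30, -20, -120, -10, 3.5, -40, 3.0)
HCN2_PROTOCOL = VoltageProtocol(-30, -40, -130, -10, 5.0, -40, 5.0)
HCN4_PROTOCOL = VoltageProtocol(-30, -30, -165, -15, 5.0, -40, 5.0)


@dataclass(frozen=True)
class ActivationDataset:
    """Tail-current amplitude vs step voltage for one cell."""

    cell_id: str
    construct: str
    condition: str
    voltage_mV: np.ndarray
    tail_pA: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage_mV, dtype=float)
        i = np.asarray(self.tail_pA, dtype=float)
        if v.shape != i.shape or v.ndim != 1:
            raise ValueError("voltage and amplitude must be matching 1-D arrays")
        if np.unique(v).size != v.size:
            raise ValueError("one amplitude per voltage per cell")
        if np.unique(v).size < 4:
            raise ValueError("need >= 4 distinct voltages to fit")
        order = np.argsort(v)
        object.__setattr__(self, "voltage_mV", v[order])
        object.__setattr__(self, "tail_pA", i[order])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["ActivationDataset"]:
        """Split a long table (cell_id, construct, condition, voltage_mV, tail_pA)."""
        out = []
        for (cell, construct, condition), grp in df.groupby(
                ["cell_id", "construct", "condition"], sort=True):
            out.append(cls(str(cell), str(construct), str(condition),
                           grp["voltage_mV"].to_numpy(float),
                           grp["tail_pA"].to_numpy(float)))
        return out


def boltzmann(v: np.ndarray, v_half: float, k_slope: float,
              amplitude: float = 1.0) -> np.ndarray:
    """A / (1 + exp((V − V1/2)/k)) — fractional activation times amplitude."""
    return amplitude / (1.0 + np.exp((np.asarray(v, float) - v_half) / k_slope))


@dataclass(frozen=True)
class BoltzmannFit:
    """Per-cell Boltzmann fit result (signed V1/2, mV)."""

    v_half: float
    k_slope: float
    amplitude: float
    v_half_se: float
    k_slope_se: float
    amplitude_se: float
    rss: float
    n_points: int
    cell_id: str = ""
    construct: str = ""
    condition: str = ""
    saturated: bool = False

    @property
    def v_half_magnitude(self) -> float:
        """|V1/2| — display convention used for hyperpolarizing channels."""
        return abs(self.v_half)

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(v, self.v_half, self.k_slope, self.amplitude)


def _boltzmann_init(v: np.ndarray, i: np.ndarray) -> tuple[float, float, float]:
    """Initial guesses: V1/2 at half-max crossing, k from the 25-75% span / 2.2."""
    a0 = float(np.max(np.abs(i)))
    if a0 == 0:
        a0 = 1.0
    # orient so activation grows toward negative voltages or positive alike
    frac = i / a0
    half_idx = int(np.argmin(np.abs(np.abs(frac) - 0.5)))
    v50 = float(v[half_idx])
    v25 = float(v[np.argmin(np.abs(np.abs(frac) - 0.25))])
    v75 = float(v[np.argmin(np.abs(np.abs(frac) - 0.75))])
    k0 = abs(v25 - v75) / 2.2
    k0 = min(max(k0, 0.6), 49.0)
    # sign of k: amplitude should decay with increasing V for channels that
    # activate on hyperpolarization (current larger at more negative steps)
    slope = np.polyfit(v, i, 1)[0]
    k0 = k0 if slope <= 0 else -k0
    return v50, k0, a0


def fit_boltzmann(dataset: ActivationDataset) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of one cell's activation data.

    Emits :class:`SaturatedDataWarning` (and flags the result) when the
    amplitudes show no inflection inside the sampled range — e.g. all
    voltages on the saturated plateau.

    Raises
    ------
    FitError
        If the optimizer does not converge.
    """
    v = dataset.voltage_mV
    i = dataset.tail_pA
    v0, k0, a0 = _boltzmann_init(v, i)

    saturated = False
    span = np.max(i) - np.min(i)
    scale = max(np.max(np.abs(i)), 1e-12)
    if span < 0.05 * scale:
        saturated = True
    else:
        # no inflection: extreme amplitudes not bracketed around half-max
        frac = (i - i.min()) / span
        if frac.min() > 0.3 or frac.max() < 0.7:
            saturated = True
    if saturated:
        warnings.warn(
            f"cell {dataset.cell_id}: activation shows no inflection in the "
            "sampled voltage range; Boltzmann parameters are unreliable",
            SaturatedDataWarning,
            stacklevel=2,
        )

    bounds = ([-np.inf, -50.0, -np.inf], [np.inf, 50.0, np.inf])

    def model(vv, v_half, k_slope, amp):
        kk = np.sign(k_slope) * max(abs(k_slope), 0.5)
        return boltzmann(vv, v_half, kk, amp)

    try:
        popt, pcov = optimize.curve_fit(
            model, v, i, p0=[v0, k0, a0], bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"Boltzmann fit failed for cell {dataset.cell_id!r}: {exc}; "
            f"init=(V1/2={v0:.1f} mV, k={k0:.1f} mV, A={a0:.1f} pA)"
        ) from exc
    v_half, k_slope, amp = popt
    k_slope = float(np.sign(k_slope) * max(abs(k_slope), 0.5))
    resid = i - model(v, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return BoltzmannFit(
        v_half=float(v_half), k_slope=k_slope, amplitude=float(amp),
        v_half_se=float(se[0]), k_slope_se=float(se[1]), amplitude_se=float(se[2]),
        rss=float(resid @ resid), n_points=len(v),
        cell_id=dataset.cell_id, construct=dataset.construct,
        condition=dataset.condition, saturated=saturated,
    )


@dataclass(frozen=True)
class ActivationSummary:
    """Mean ± SEM of per-cell Boltzmann parameters."""

    n: int
    v_half_mean: float
    v_half_sem: float
    k_mean: float
    k_sem: float


def mean_activation(fits: Sequence[BoltzmannFit]) -> ActivationSummary:
    """Average per-cell fits (the per-cell-then-average convention).

    SEM is NaN for a single cell.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    vh = np.array([f.v_half for f in fits])
    kk = np.array([f.k_slope for f in fits])
    n = len(fits)
    sem = (lambda x: float(np.std(x, ddof=1) / np.sqrt(n))) if n > 1 else (
        lambda x: float("nan"))
    return ActivationSummary(n=n,
                             v_half_mean=float(vh.mean()), v_half_sem=sem(vh),
                             k_mean=float(kk.mean()), k_sem=sem(kk))


@dataclass(frozen=True)
class KineticsFit:
    """Single-exponential fit I = I0·exp(−t/τ)."""

    tau: float        # same unit as the time axis
    i0: float         # pA
    window: tuple[float, float]
    rss: float
    n_points: int


def fit_exponential(t: np.ndarray, i: np.ndarray,
                    window: tuple[float, float] | None = None) -> KineticsFit:
    """Least-squares mono-exponential fit on a time window (>= 10 samples)."""
    t = np.asarray(t, dtype=float)
    i = np.asarray(i, dtype=float)
    if t.shape != i.shape or t.ndim != 1:
        raise ValueError("t and I must be matching 1-D arrays")
    if window is None:
        window = (float(t[0]), float(t[-1]))
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 10:
        raise ValueError(
            f"window [{lo}, {hi}] holds {int(mask.sum())} samples; need >= 10"
        )
    tw, iw = t[mask], i[mask]
    t0 = tw[0]
    i0_guess = iw[0] if iw[0] != 0 else (np.max(np.abs(iw)) or 1.0)
    # crude τ guess: time to decay to 1/e of the initial value
    target = abs(i0_guess) / np.e
    below = np.flatnonzero(np.abs(iw) <= target)
    tau0 = (tw[below[0]] - t0) if below.size else (tw[-1] - t0) / 2
    tau0 = max(tau0, (tw[1] - tw[0]))

    def model(tt, i0, tau):
        return i0 * np.exp(-(tt - t0) / tau)

    try:
        popt, _ = optimize.curve_fit(model, tw, iw, p0=[i0_guess, tau0],
                                     maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    i0, tau = popt
    if tau <= 0:
        raise FitError(f"exponential fit returned non-positive tau ({tau:g})")
    resid = iw - model(tw, *popt)
    return KineticsFit(tau=float(tau), i0=float(i0), window=(float(lo), float(hi)),
                       rss=float(resid @ resid), n_points=int(mask.sum()))


def delta_g_app(v_half: float, k_slope: float,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Apparent gating free energy ΔGapp = (RT/k)·V1/2, kcal/mol.

    V1/2 and k must be in the same voltage units (their ratio is
    dimensionless); R = 1.987e-3 kcal/(mol·K).
    """
    if k_slope == 0:
        raise ZeroDivisionError("inverse slope factor k must be nonzero")
    return R_KCAL * temperature * v_half / k_slope


@dataclass(frozen=True)
class ConstructEnergetics:
    """One construct's activation parameters and apparent gating energy."""

    construct: str
    v_half: float                  # mV, signed
    k_slope: float                 # mV
    temperature: float = DEFAULT_TEMPERATURE
    dg_app: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "dg_app",
            delta_g_app(self.v_half, self.k_slope, self.temperature))


def construct_energetics(construct: str, fits: Sequence[BoltzmannFit],
                         temperature: float = DEFAULT_TEMPERATURE
                         ) -> ConstructEnergetics:
    """Energetics from per-cell fits: mean V1/2 and k across cells."""
    summary = mean_activation(fits)
    return ConstructEnergetics(construct, summary.v_half_mean, summary.k_mean,
                               temperature)


@dataclass(frozen=True)
class MutantCycle:
    """Thermodynamic double-mutant cycle over four constructs.

    ``ddg`` is the non-additivity ΔΔG = ΔGapp(wt) + ΔGapp(double)
    − ΔGapp(single1) − ΔGapp(single2); ``dg_p`` holds the perturbation
    energies along each edge of the cycle. ``coupled`` flags
    |ΔΔG| > threshold.
    """

    wt: ConstructEnergetics
    single1: ConstructEnergetics
    single2: ConstructEnergetics
    double: ConstructEnergetics
    dg_p: dict[str, float]
    ddg: float
    coupled: bool
    threshold: float


def mutant_cycle(wt: ConstructEnergetics,
                 single1: ConstructEnergetics,
                 single2: ConstructEnergetics,
                 double: ConstructEnergetics,
                 coupling_threshold: float = 1.0) -> MutantCycle:
    """Assemble the four-construct cycle and its coupling energy.

    All constructs must share a temperature. The two routes around the
    cycle give perturbation-energy differences equal to ±ΔΔG; both edges
    are reported.
    """
    temps = {wt.temperature, single1.temperature, single2.temperature,
             double.temperature}
    if len(temps) != 1:
        raise ValueError(f"temperature mismatch across constructs: {sorted(temps)}")
    dg_p = {
        f"{wt.construct}->{single1.construct}": single1.dg_app - wt.dg_app,
        f"{wt.construct}->{single2.construct}": single2.dg_app - wt.dg_app,
        f"{single1.construct}->{double.construct}": double.dg_app - single1.dg_app,
        f"{single2.construct}->{double.construct}": double.dg_app - single2.dg_app,
    }
    ddg = wt.dg_app + double.dg_app - single1.dg_app - single2.dg_app
    return MutantCycle(wt=wt, single1=single1, single2=single2, double=double,
                       dg_p=dg_p, ddg=float(ddg),
                       coupled=abs(ddg) > coupling_threshold,
                       threshold=coupling_threshold)


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA (or t-test) over groups, with Fisher's LSD post-hoc."""

    method: str                       # "anova+lsd" or "t-test"
    statistic: float                  # F or t
    p_value: float
    alpha: float
    significant: bool
    pairwise: dict[tuple[str, str], float] | None
    degenerate: bool = False


def compare_groups(groups: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> GroupComparison:
    """Compare group means the way activation parameters are compared.

    Two groups: Student's t-test. Three or more: one-way ANOVA; pairwise
    Fisher's-LSD p-values (t on the pooled within-group variance) are
    computed only when the ANOVA is significant at ``alpha``.
    """
    names = list(groups)
    data = [np.asarray(groups[n], dtype=float) for n in names]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(d) < 2 for d in data):
        raise ValueError("every group needs n >= 2")
    degenerate = all(np.ptp(d) == 0 for d in data)
    if len(data) == 2:
        if degenerate:
            return GroupComparison("t-test", float("nan"), float("nan"),
                                   alpha, False, None, True)
        t, p = stats.ttest_ind(data[0], data[1])
        return GroupComparison("t-test", float(t), float(p), alpha,
                               bool(p < alpha), None)
    if degenerate:
        return GroupComparison("anova+lsd", float("nan"), float("nan"),
                               alpha, False, None, True)
    f, p = stats.f_oneway(*data)
    pairwise = None
    if p < alpha:
        # Fisher's LSD: pairwise t with the pooled within-group variance
        n_total = sum(len(d) for d in data)
        df_w = n_total - len(data)
        mse = sum(((d - d.mean()) ** 2).sum() for d in data) / df_w
        pairwise = {}
        for a in range(len(data)):
            for b in range(a + 1, len(data)):
                se = np.sqrt(mse * (1 / len(data[a]) + 1 / len(data[b])))
                t_ab = (data[a].mean() - data[b].mean()) / se
                pairwise[(names[a], names[b])] = float(
                    2 * stats.t.sf(abs(t_ab), df_w))
    return GroupComparison("anova+lsd", float(f), float(p), alpha,
                           bool(p < alpha), pairwise)


def camp_shift(summary_control: ActivationSummary,
               summary_camp: ActivationSummary) -> tuple[float, float]:
    """cAMP-induced V1/2 shift (cAMP − control, mV) with SEM by quadrature."""
    shift = summary_camp.v_half_mean - summary_control.v_half_mean
    sem = float(np.sqrt(np.nan_to_num(summary_control.v_half_sem) ** 2
                        + np.nan_to_num(summary_camp.v_half_sem) ** 2))
    return float(shift), sem
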