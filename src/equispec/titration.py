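"""Potentiometric titration: forward simulation, Gran endpoints, calibration.

The forward model dilutes every analytical total by V0/(V0+V), adds the
titrant contribution -c_t*V/(V0+V) to the proton total (strong base titrant
positive by convention; a strong-acid titrant is encoded with negative
concentration), and solves the full proton mass balance including the water
term h - Kw/h at every point.

Electrode convention (used everywhere in this package):

    E = E0 + s * log10[H+],   s ~ +59.16 mV/decade at 298 K,

i.e. the slope is written against log10 of the hydrogen-ion *concentration*
(the electrodes are calibrated for concentration, not activity), and emf
decreases as pH rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._solver import solve_equilibrium
from .exceptions import (
    CalibrationError,
    ConvergenceError,
    GranError,
    ModelError,
)
from .model import EquilibriumModel

NERNST_SLOPE_25C = 59.16  # mV per decade at 298 K


@dataclass
class TitrationProtocol:
    """Experimental design of one titration."""

    initial_volume_mL: float
    initial_totals: dict[str, float]  # mol/dm3 in the initial solution; "H" net acid
    titrant_concentration_M: float  # strong base > 0; strong acid < 0
    volume_points_mL: np.ndarray
    temperature_K: float = 298.0
    ionic_strength_M: float = 0.1

    def __post_init__(self) -> None:
        self.volume_points_mL = np.asarray(self.volume_points_mL, dtype=float)
        if self.initial_volume_mL <= 0:
            raise ModelError("initial volume must be positive")
        v = self.volume_points_mL
        if v.size and (v[0] < 0 or np.any(np.diff(v) <= 0)):
            raise ModelError("titrant volumes must be strictly increasing and >= 0")

    def totals_at(self, v_mL: float, proton: str = "H") -> dict[str, float]:
        """Diluted analytical totals after adding ``v_mL`` of titrant."""
        v0 = self.initial_volume_mL
        dil = v0 / (v0 + v_mL)
        totals = {
            name: conc * dil
            for name, conc in self.initial_totals.items()
            if name != proton
        }
        th0 = self.initial_totals.get(proton, 0.0)
        totals[proton] = (th0 * v0 - self.titrant_concentration_M * v_mL) / (v0 + v_mL)
        return totals


@dataclass
class ElectrodeParams:
    """Glass-electrode response: E = E0 + slope * log10[H+]."""

    E0_mV: float
    slope_mV: float = NERNST_SLOPE_25C
    sigma_E0: float | None = None
    sigma_slope: float | None = None

    def emf(self, h: float | np.ndarray) -> float | np.ndarray:
        return self.E0_mV + self.slope_mV * np.log10(h)

    def h_from_emf(self, emf_mV: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** ((np.asarray(emf_mV) - self.E0_mV) / self.slope_mV)


@dataclass
class TitrationDataset:
    """Ordered (added volume, observed value) points of one titration."""

    volumes_mL: np.ndarray
    values: np.ndarray
    kind: str  # "pH" or "emf_mV"
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volumes_mL = np.asarray(self.volumes_mL, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("pH", "emf_mV"):
            raise ModelError(f"dataset kind must be 'pH' or 'emf_mV', got {self.kind!r}")
        if self.volumes_mL.size < 4:
            raise ModelError("a titration dataset needs at least 4 points")
        if self.volumes_mL.size != self.values.size:
            raise ModelError("volumes and values differ in length")
        if np.any(np.diff(self.volumes_mL) <= 0):
            raise ModelError("titrant volumes must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)

    def __len__(self) -> int:
        return int(self.volumes_mL.size)


def _solve_full_point(
    model: EquilibriumModel,
    totals: Mapping[str, float],
    *,
    warm: np.ndarray | None = None,
) -> tuple[float, dict[str, float], np.ndarray]:
    """Solve the mass balances with the proton as an unknown (water term on)."""
    proton = model.proton_name
    active = [proton]
    excluded = []
    for comp in model.components:
        if comp.name == proton:
            continue
        t = float(totals.get(comp.name, 0.0))
        if t < 0:
            raise ModelError(f"total for {comp.name!r} must be >= 0")
        (active if t > 0 else excluded).append(comp.name)
    species = [
        sp for sp in model.species if not any(sp.coeff(n) for n in excluded)
    ]
    nu = np.array(
        [[sp.coeff(name) for name in active] for sp in species], dtype=float
    ).reshape(len(species), len(active))
    log_beta = np.array([sp.log_beta for sp in species], dtype=float)
    tvec = np.array([float(totals.get(name, 0.0)) for name in active], dtype=float)
    x, _ = solve_equilibrium(
        log_beta,
        nu,
        tvec,
        proton_index=0,
        Kw=10.0**-model.pKw,
        y0=warm,
    )
    h = float(x[0])
    free = dict(zip(active, x.tolist()))
    return h, free, np.log(x)


def simulate_titration(
    model: EquilibriumModel,
    protocol: TitrationProtocol,
    electrode: ElectrodeParams | None = None,
) -> TitrationDataset:
    """Noiseless, deterministic forward simulation of a titration.

    Returns pH values, or emf in mV when ``electrode`` is given.
    """
    proton = model.proton_name
    values = np.empty(protocol.volume_points_mL.size)
    warm = None
    for i, v in enumerate(protocol.volume_points_mL):
        totals = protocol.totals_at(v, proton=proton)
        try:
            h, _, warm = _solve_full_point(model, totals, warm=warm)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"titration simulation failed at V = {v:.4f} mL: {exc}",
                residual=exc.residual,
            ) from exc
        values[i] = -np.log10(h)
    if electrode is not None:
        values = electrode.emf(10.0**-values)
        kind = "emf_mV"
    else:
        kind = "pH"
    return TitrationDataset(
        volumes_mL=protocol.volume_points_mL.copy(),
        values=values,
        kind=kind,
        sigma=np.zeros_like(values),
        metadata={"model": model.label, "noiseless": True},
    )


@dataclass
class GranResult:
    equivalence_volume_mL: float
    stderr_mL: float
    n_points: int
    window: tuple[int, int]  # index range [start, stop) used for the fit


def gran_endpoint(
    dataset: TitrationDataset,
    v0_mL: float,
    *,
    electrode: ElectrodeParams | None = None,
    branch: str = "acid",
    pKw: float = 13.78,
    window: tuple[float, float] = (0.2, 0.8),
) -> GranResult:
    """Equivalence volume from the Gran linearization.

    The acid-branch Gran function F = (V0+V) * [H+] decays linearly to zero
    at the equivalence volume; the base branch uses (V0+V) * Kw/[H+].  A
    straight line is fitted over the points whose F lies within the
    ``window`` fractions of the branch maximum (default 20-80 %, standard
    practice) and its volume-axis intercept is returned with the standard
    error propagated from the fit.
    """
    if branch not in ("acid", "base"):
        raise GranError(f"branch must be 'acid' or 'base', got {branch!r}")
    v = dataset.volumes_mL
    if dataset.kind == "pH":
        h = 10.0 ** (-dataset.values)
    else:
        if electrode is None:
            raise GranError("emf dataset requires electrode parameters")
        h = np.asarray(electrode.h_from_emf(dataset.values), dtype=float)
    proxy = h if branch == "acid" else 10.0**-pKw / h
    F = (v0_mL + v) * proxy

    lo, hi_frac = window
    fmax = float(F.max())
    mask = (F >= lo * fmax) & (F <= hi_frac * fmax)
    if mask.sum() < 2:
        raise GranError("fewer than 2 points in the Gran window; widen the window")
    idx = np.flatnonzero(mask)
    vw, fw = v[idx], F[idx]
    diffs = np.diff(fw)
    if not (np.all(diffs < 0) or np.all(diffs > 0)):
        raise GranError(
            "Gran function is not monotone over the selected window; "
            "choose a different window"
        )
    slope, intercept = np.polyfit(vw, fw, 1)
    veq = -intercept / slope
    if len(vw) > 2:
        resid = fw - (slope * vw + intercept)
        dof = len(vw) - 2
        s2 = float(resid @ resid) / dof
        sxx = float(((vw - vw.mean()) ** 2).sum())
        var_slope = s2 / sxx
        var_intercept = s2 * (1.0 / len(vw) + vw.mean() ** 2 / sxx)
        cov_ab = -s2 * vw.mean() / sxx
        # Veq = -b/a; gradient (b/a^2, -1/a)
        g_a, g_b = intercept / slope**2, -1.0 / slope
        var = g_a**2 * var_slope + g_b**2 * var_intercept + 2 * g_a * g_b * cov_ab
        stderr = float(np.sqrt(max(var, 0.0)))
    else:
        stderr = 0.0
    return GranResult(
        equivalence_volume_mL=float(veq),
        stderr_mL=stderr,
        n_points=int(len(vw)),
        window=(int(idx[0]), int(idx[-1]) + 1),
    )


def calibrate_electrode(
    dataset: TitrationDataset,
    protocol: TitrationProtocol,
    *,
    pKw: float = 13.78,
    exclude_mL: float = 0.02,
    min_points: int = 3,
) -> ElectrodeParams:
    """Electrode standard potential and slope from a strong-acid titration.

    The model hydrogen-ion concentration at each point follows from the
    strong-acid/strong-base balance C_H = h - Kw/h, solved in closed form,
    and E is regressed on log10[H+].  Points within ``exclude_mL`` of the
    equivalence volume are excluded (the balance is ill-conditioned there).
    """
    if dataset.kind != "emf_mV":
        raise CalibrationError("electrode calibration requires an emf dataset")
    extra = {
        name: conc
        for name, conc in protocol.initial_totals.items()
        if name != "H" and conc != 0.0
    }
    if extra:
        raise CalibrationError(
            f"calibration protocol must contain strong acid only; found totals {extra}"
        )
    Kw = 10.0**-pKw
    v = dataset.volumes_mL
    v0 = protocol.initial_volume_mL
    th0 = protocol.initial_totals.get("H", 0.0)
    ct = protocol.titrant_concentration_M
    C = (th0 * v0 - ct * v) / (v0 + v)
    h = (C + np.sqrt(C**2 + 4.0 * Kw)) / 2.0
    veq = th0 * v0 / ct if ct != 0 else np.inf
    usable = np.abs(v - veq) > exclude_mL
    if usable.sum() < min_points:
        raise CalibrationError(
            f"only {int(usable.sum())} usable points (need >= {min_points}); "
            "reduce the exclusion buffer"
        )
    res = stats.linregress(np.log10(h[usable]), dataset.values[usable])
    slope, e0 = float(res.slope), float(res.intercept)
    if not (50.0 <= abs(slope) <= 62.0):
        raise CalibrationError(
            f"calibrated slope {slope:.2f} mV/decade outside the Nernstian "
            "acceptance band [50, 62]"
        )
    return ElectrodeParams(
        E0_mV=e0,
        slope_mV=slope,
        sigma_E0=float(res.intercept_stderr),
        sigma_slope=float(res.stderr),
    )
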