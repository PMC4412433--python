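"""Synthetic DSC-MRI curve populations with known ground truth.

The digital phantom emulates a single perfusion slice as a population of
per-voxel time curves: a handful of "true" arterial voxels carrying the
arterial input function (AIF), delayed/dispersed "false" arterial voxels,
three tissue compartments (normal grey matter, pathological grey matter,
normal white matter), and voxels contaminated by the partial volume effect
(PVE).  The first bolus passage is a gamma-variate; a delayed, exponentially
dispersed copy models recirculation; tissue curves follow indicator-dilution
theory (convolution of the AIF with a scaled exponential residue function);
signals are obtained through the T2* susceptibility model and corrupted with
Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_model import SignalModelParams, calibrate_kappa, signal_from_concentration

__all__ = [
    "SamplingGrid",
    "GammaVariateParams",
    "RecirculationParams",
    "TissueParams",
    "PhantomSpec",
    "CurveSet",
    "Phantom",
    "CLASS_ORDER",
    "gamma_variate",
    "add_recirculation",
    "tissue_concentration",
    "mix_pve",
    "build_phantom",
]

#: Row ordering of voxel classes in a built phantom.
CLASS_ORDER = ("arterial", "false_arterial", "gm", "gm_path", "wm", "pve")


@dataclass(frozen=True)
class SamplingGrid:
    """Uniform acquisition grid: frame ``i`` (1-based) is sampled at ``i * tr``.

    Defaults mirror a typical single-shot EPI perfusion protocol: 60 frames,
    TR = 1.5 s, TE = 0.03 s, so the grid spans 1.5-90 s.
    """

    n_frames: int = 60
    tr: float = 1.5
    te: float = 0.03

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not (self.tr > 0 and self.te > 0):
            raise ValueError("TR and TE must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1, dtype=float) * self.tr

    @property
    def duration(self) -> float:
        return self.n_frames * self.tr


def _times_of(grid) -> np.ndarray:
    """Accept a SamplingGrid or a raw (uniform, increasing) time vector."""
    if isinstance(grid, SamplingGrid):
        return grid.times
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time vector must be 1-D with at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-8):
        raise ValueError("times must be uniformly spaced")
    return t


@dataclass(frozen=True)
class GammaVariateParams:
    """First-passage bolus model ``scale * (t-t0)^alpha * exp(-(t-t0)/beta)``.

    ``alpha`` reflects vascular architecture, ``beta`` blood flow; ``t0`` is
    the bolus arrival time.  The proportionality constant is ``scale``.
    """

    t0: float = 26.0
    alpha: float = 3.0
    beta: float = 1.5
    scale: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.t0, self.alpha, self.beta, self.scale)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("gamma-variate parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0 or self.scale <= 0 or self.t0 < 0:
            raise ValueError("require alpha, beta, scale > 0 and t0 >= 0")

    @property
    def peak_time(self) -> float:
        """Continuous-time maximum, at ``t0 + alpha * beta``."""
        return self.t0 + self.alpha * self.beta

    @property
    def peak_value(self) -> float:
        return self.scale * (self.alpha * self.beta) ** self.alpha * math.exp(-self.alpha)

    @property
    def area(self) -> float:
        """Analytic area ``scale * Gamma(alpha+1) * beta**(alpha+1)``."""
        return self.scale * math.gamma(self.alpha + 1.0) * self.beta ** (self.alpha + 1.0)


@dataclass(frozen=True)
class RecirculationParams:
    """Second-passage model: the first passage delayed by ``tau_d`` and
    convolved with an exponential kernel of time constant ``tau_r``.

    With ``kernel_normalized`` the kernel is scaled to unit discrete area, so
    the recirculation contributes ``amplitude`` times the first-passage area.
    """

    tau_d: float = 8.0
    tau_r: float = 30.0
    kernel_normalized: bool = True
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_d <= 0 or self.tau_r <= 0:
            raise ValueError("tau_d and tau_r must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class TissueParams:
    """Perfusion state of one tissue class.

    CBV in ml/100 g; MTT mean and per-voxel standard deviation in seconds.
    CBF follows from the central volume principle, CBF = CBV / MTT.
    """

    cbv: float
    mtt_mean: float
    mtt_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.cbv <= 0 or self.mtt_mean <= 0 or self.mtt_sd < 0:
            raise ValueError("require cbv, mtt_mean > 0 and mtt_sd >= 0")

    @property
    def cbf(self) -> float:
        """Nominal CBF = CBV / MTT (ml/100 g/s)."""
        return self.cbv / self.mtt_mean


#: Default tissue states (CBV ml/100 g, MTT mean +/- sd seconds).
DEFAULT_TISSUES: dict[str, TissueParams] = {
    "gm": TissueParams(cbv=4.0, mtt_mean=4.0, mtt_sd=0.33),
    "gm_path": TissueParams(cbv=3.3, mtt_mean=10.0, mtt_sd=0.7),
    "wm": TissueParams(cbv=2.0, mtt_mean=5.45, mtt_sd=0.33),
}

DEFAULT_COMPOSITION: dict[str, int] = {
    "arterial": 6,
    "false_arterial": 16,
    "gm": 440,
    "gm_path": 440,
    "wm": 600,
    "pve": 400,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to build one phantom realization.

    ``false_t0_range`` / ``false_tau_d_range`` are (start, stop, step)
    triples, stop inclusive; the false-arterial class enumerates their
    Cartesian product.  ``snr = S0 / sigma`` sets the Gaussian signal noise;
    ``snr=None`` disables noise.  ``noise_subset`` restricts noise to a
    random subset of that many curves, emulating a protocol in which noise
    corrupts 400 randomly extracted curves of the slice; ``None`` corrupts
    every curve.  ``tissue_scale`` is the unit-conversion constant between
    CBF·(AIF⊗R) and measured concentration; see docs/methods.md.
    """

    grid: SamplingGrid = field(default_factory=SamplingGrid)
    aif_params: GammaVariateParams = field(default_factory=GammaVariateParams)
    recirc: RecirculationParams = field(default_factory=RecirculationParams)
    composition: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    tissue_params: dict[str, TissueParams] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    false_t0_range: tuple[float, float, float] = (27.0, 30.0, 1.0)
    false_tau_d_range: tuple[float, float, float] = (9.0, 12.0, 1.0)
    snr: float | None = 20.0
    s0: float = 100.0
    tissue_scale: float = 0.1
    target_gm_drop: float = 0.40
    noise_subset: int | None = 400
    signal_floor: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None to disable noise)")
        if self.s0 <= 0 or self.tissue_scale <= 0 or self.signal_floor <= 0:
            raise ValueError("s0, tissue_scale and signal_floor must be positive")
        if any(c < 0 for c in self.composition.values()):
            raise ValueError("composition counts must be non-negative")

    def false_arterial_grid(self) -> list[tuple[float, float]]:
        """Cartesian (t0, tau_d) grid for the false-arterial class."""

        def _steps(rng: tuple[float, float, float]) -> np.ndarray:
            start, stop, step = rng
            n = int(round((stop - start) / step)) + 1
            return start + step * np.arange(n)

        return [(float(a), float(b))
                for a in _steps(self.false_t0_range)
                for b in _steps(self.false_tau_d_range)]

    @property
    def n_curves(self) -> int:
        return sum(self.composition.values())


@dataclass
class CurveSet:
    """A matrix of per-voxel time curves plus per-curve class labels.

    ``units`` is ``"signal"`` or ``"concentration"``; labels are the phantom
    class names, or ``"unknown"`` for clinical data.
    """

    values: np.ndarray
    labels: np.ndarray
    grid: SamplingGrid
    units: str = "signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_curves, n_frames) matrix")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("row count must equal label count")
        if self.values.shape[1] != self.grid.n_frames:
            raise ValueError("column count must equal grid.n_frames")
        if self.units not in ("signal", "concentration"):
            raise ValueError("units must be 'signal' or 'concentration'")
        if self.units == "signal" and np.any(self.values < 0):
            raise ValueError("signal-unit values must be non-negative")

    @property
    def n_curves(self) -> int:
        return self.values.shape[0]


@dataclass
class Phantom:
    """A built phantom: signal curves, the noiseless true AIF (concentration
    units), and the calibrated signal model used to generate the signals."""

    curves: CurveSet
    true_aif: np.ndarray
    signal_params: SignalModelParams
    spec: PhantomSpec


def gamma_variate(grid, params: GammaVariateParams) -> np.ndarray:
    """Evaluate the gamma-variate first passage on a time grid.

    Exactly zero for ``t <= t0``.
    """
    t = _times_of(grid)
    x = t - params.t0
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = params.scale * x[pos] ** params.alpha * np.exp(-x[pos] / params.beta)
    return out


def add_recirculation(first_passage: np.ndarray, recirc: RecirculationParams, grid,
                      onset: float | None = None) -> np.ndarray:
    """Add a recirculation passage to a sampled first-passage curve.

    The first passage is delayed by ``tau_d`` (linear interpolation of the
    samples) and convolved with an exponential kernel ``exp(-t/tau_r)``
    discretized on the grid step; the result, times ``amplitude``, is added
    to the first passage.  ``onset`` (the bolus arrival time, if known)
    zeroes interpolation leakage below arrival so the contribution is
    exactly zero for ``t <= onset + tau_d``.
    """
    t = _times_of(grid)
    fp = np.asarray(first_passage, dtype=float)
    if fp.shape != t.shape:
        raise ValueError("first_passage must be sampled on the given grid")
    if recirc.amplitude == 0.0:
        return fp.copy()
    dt = t[1] - t[0]
    delayed = np.interp(t - recirc.tau_d, t, fp, left=0.0)
    if onset is not None:
        delayed[t - recirc.tau_d <= onset] = 0.0
    kernel = np.exp(-np.arange(t.size) * dt / recirc.tau_r)
    if recirc.kernel_normalized:
        kernel = kernel / (kernel.sum() * dt)
    else:
        kernel = kernel / recirc.tau_r
    contribution = recirc.amplitude * np.convolve(delayed, kernel)[: t.size] * dt
    return fp + contribution


_MTT_MAX_RETRIES = 16


def tissue_concentration(aif: np.ndarray, tissue: TissueParams, grid,
                         rng: np.random.Generator | None = None,
                         tissue_scale: float = 0.1,
                         mtt: float | None = None) -> np.ndarray:
    """Tissue time-concentration curve by indicator dilution.

    ``C_t = tissue_scale * CBF * (AIF ⊗ R)`` with exponential residue
    ``R(t) = exp(-t/MTT)``, discretized with the grid spacing as integration
    step.  The voxel's MTT is drawn as ``N(mtt_mean, mtt_sd)`` from ``rng``
    (pass ``mtt`` to fix it, e.g. for the nominal calibration curve); CBF is
    the voxel's CBV / MTT.
    """
    t = _times_of(grid)
    aif = np.asarray(aif, dtype=float)
    if aif.shape != t.shape:
        raise ValueError("aif must be sampled on the given grid")
    if mtt is None:
        if tissue.mtt_sd == 0.0 or rng is None:
            mtt = tissue.mtt_mean
        else:
            for _ in range(_MTT_MAX_RETRIES):
                mtt = tissue.mtt_mean + tissue.mtt_sd * rng.standard_normal()
                if mtt > 0:
                    break
            else:
                raise ValueError("could not draw a positive MTT")
    if mtt <= 0:
        raise ValueError("MTT must be positive")
    dt = t[1] - t[0]
    cbf = tissue.cbv / mtt
    residue = np.exp(-np.arange(t.size) * dt / mtt)
    return tissue_scale * cbf * np.convolve(aif, residue)[: t.size] * dt


def mix_pve(arterial: np.ndarray, tissue: np.ndarray,
            rng: np.random.Generator | None = None,
            w: float | None = None) -> np.ndarray:
    """Partial-volume mixture ``w*arterial + (1-w)*tissue`` with a random
    uniform weight (both curves must share grid and units)."""
    arterial = np.asarray(arterial, dtype=float)
    tissue = np.asarray(tissue, dtype=float)
    if arterial.shape != tissue.shape:
        raise ValueError("curves must share the same grid")
    if w is None:
        if rng is None:
            raise ValueError("provide either rng or an explicit weight w")
        w = float(rng.uniform())
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixture weight must lie in [0, 1]")
    return w * arterial + (1.0 - w) * tissue


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Build one phantom realization.

    Returns signal-unit curves for all configured classes (row order:
    arterial, false arterial, normal GM, pathological GM, normal WM, PVE)
    together with the noiseless true AIF in concentration units and the
    calibrated signal model.  Identical specs (same seed) produce
    bit-identical phantoms.
    """
    grid = spec.grid
    comp = spec.composition
    rng = np.random.default_rng(spec.seed)

    fgrid = spec.false_arterial_grid()
    n_false = comp.get("false_arterial", 0)
    if n_false not in (0, len(fgrid)):
        raise ValueError(
            f"false_arterial count {n_false} inconsistent with the "
            f"{len(fgrid)}-combination (t0, tau_d) grid")

    # --- concentration-unit curves -------------------------------------
    fp = gamma_variate(grid, spec.aif_params)
    true_aif = add_recirculation(fp, spec.recirc, grid, onset=spec.aif_params.t0)

    conc_rows: list[np.ndarray] = []
    labels: list[str] = []

    for _ in range(comp.get("arterial", 0)):
        conc_rows.append(true_aif)
        labels.append("arterial")

    if n_false:
        for t0_f, tau_d_f in fgrid:
            p = replace(spec.aif_params, t0=t0_f)
            r = replace(spec.recirc, tau_d=tau_d_f)
            curve = add_recirculation(gamma_variate(grid, p), r, grid, onset=t0_f)
            conc_rows.append(curve)
            labels.append("false_arterial")

    tissue_classes = [c for c in ("gm", "gm_path", "wm") if comp.get(c, 0) > 0]
    for cls in tissue_classes:
        tp = spec.tissue_params[cls]
        for _ in range(comp[cls]):
            conc_rows.append(tissue_concentration(true_aif, tp, grid, rng,
                                                  tissue_scale=spec.tissue_scale))
            labels.append(cls)

    # --- calibrate susceptibility constant on the nominal GM curve ------
    gm_nominal = tissue_concentration(true_aif, spec.tissue_params["gm"], grid,
                                      tissue_scale=spec.tissue_scale,
                                      mtt=spec.tissue_params["gm"].mtt_mean)
    kappa = calibrate_kappa(float(gm_nominal.max()), grid.te, spec.target_gm_drop)
    sp = SignalModelParams(s0=spec.s0, kappa_vox=kappa, te=grid.te)

    signal_rows = [signal_from_concentration(c, sp) for c in conc_rows]

    # --- PVE mixtures (mixed in signal units) ---------------------------
    arterial_signal = signal_from_concentration(true_aif, sp)
    mix_classes = tissue_classes or ["gm"]
    for _ in range(comp.get("pve", 0)):
        cls = mix_classes[rng.integers(len(mix_classes))]
        tp = spec.tissue_params[cls]
        tissue_sig = signal_from_concentration(
            tissue_concentration(true_aif, tp, grid, rng,
                                 tissue_scale=spec.tissue_scale), sp)
        signal_rows.append(mix_pve(arterial_signal, tissue_sig, rng))
        labels.append("pve")

    values = np.vstack(signal_rows)

    # --- Gaussian signal noise at SNR = S0 / sigma ----------------------
    if spec.snr is not None:
        sigma = spec.s0 / spec.snr
        if spec.noise_subset is None:
            values = values + sigma * rng.standard_normal(values.shape)
        else:
            idx = rng.choice(values.shape[0], size=min(spec.noise_subset, values.shape[0]),
                             replace=False)
            values[idx] += sigma * rng.standard_normal((idx.size, values.shape[1]))
        np.clip(values, spec.signal_floor, None, out=values)

    curves = CurveSet(values=values, labels=np.array(labels), grid=grid, units="signal")
    return Phantom(curves=curves, true_aif=true_aif, signal_params=sp, spec=spec)
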