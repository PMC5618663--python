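"""Seeded generators of synthetic photoswitching data.

Everything the downstream stages consume can be generated here with known
ground truth: repeated-switching fluorescence traces of a two-species RSFP
ensemble (with per-cycle interconversion and photodestruction), thermal
recovery traces, pH-titration absorbance tables, and rendered colony image
stacks for the extraction stage.  All randomness flows from a single seeded
``numpy.random.Generator`` per invocation, so identical configuration and
seed reproduce identical arrays.

Default parameters describe the reference experiments the package targets:
a 500-cycle protocol of 25 on + 25 off periods of 100 ms (cultured cells)
and a single 20 on / 40 off / 20 on cycle of 30 s periods (bacterial
colonies), with EMCCD-like shot + read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import SwitchingExperiment, SwitchingProtocol
from .kinetics import TwoStateKinetics
from .populations import PopulationDynamicsParams, population_closed_form

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "ColonyLayout",
    "default_truth",
    "simulate_traces",
    "simulate_recovery_trace",
    "simulate_titration",
    "render_colony_stack",
    "random_layout",
    "reference_field_experiment",
]


@dataclass(frozen=True)
class NoiseModel:
    """EMCCD-style acquisition noise.

    The expected signal (plus ``background`` offset) is converted to photons
    at ``shot_scale`` photons per intensity unit, Poisson-sampled, scaled
    back, and additive Gaussian read noise of ``read_sigma`` is applied.
    ``shot_scale = 0`` disables shot noise; ``read_sigma = 0`` disables read
    noise.
    """

    shot_scale: float = 1000.0
    read_sigma: float = 0.01
    background: float = 0.05

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.shot_scale, self.read_sigma, self.background)):
            raise ValueError("noise parameters must be finite")
        if self.shot_scale < 0 or self.read_sigma < 0:
            raise ValueError("shot_scale and read_sigma must be >= 0")

    @property
    def enabled(self) -> bool:
        return self.shot_scale > 0 or self.read_sigma > 0

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample a noisy realization of the expected signal (background added)."""
        expected = np.asarray(expected, dtype=float) + self.background
        out = expected.copy()
        if self.shot_scale > 0:
            out = rng.poisson(np.clip(expected, 0, None) * self.shot_scale) / self.shot_scale
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return out

    def to_dict(self) -> dict:
        return {
            "shot_scale": self.shot_scale,
            "read_sigma": self.read_sigma,
            "background": self.background,
        }

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(shot_scale=0.0, read_sigma=0.0, background=0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Complete generative description of a synthetic switching experiment."""

    kinetics: TwoStateKinetics
    popdyn: PopulationDynamicsParams
    noise: NoiseModel
    seed: int

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")

    def to_dict(self) -> dict:
        return {
            "kinetics": self.kinetics.to_dict(),
            "popdyn": self.popdyn.to_dict(),
            "noise": self.noise.to_dict(),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            kinetics=TwoStateKinetics(**d["kinetics"]),
            popdyn=PopulationDynamicsParams(**d["popdyn"]),
            noise=NoiseModel(**d["noise"]),
            seed=int(d["seed"]),
        )


def default_truth(seed: int, noise: NoiseModel | None = None) -> GroundTruth:
    """Reference ground truth for the 100 ms / 500-cycle protocol.

    The fast species switches off almost completely within a few frames
    (k_A = 6 s^-1) while the slow species (k_B = 1 s^-1) reaches its 15%
    residual plateau near the end of the 2.5 s off half-cycle — the plateau
    must be approached within the window for the residual fraction to be a
    measurable quantity, which is also what makes the per-cycle baseline
    (maximally off-switched frame) track b_n * f_B.  Per-cycle population
    rates depopulate A over a few hundred cycles while B rises then falls.
    """
    return GroundTruth(
        kinetics=TwoStateKinetics(k_A=6.0, k_B=1.0, f_A=0.0, f_B=0.15, c=0.02),
        popdyn=PopulationDynamicsParams(
            k_AB=0.006, k_dA=0.004, k_dB=0.004, a0=1.0, b0=0.05
        ),
        noise=NoiseModel() if noise is None else noise,
        seed=seed,
    )


def reference_field_experiment(
    seed: int,
    n_cycles: int = 500,
    n_objects: int = 20,
    noise: NoiseModel | None = None,
    truth: GroundTruth | None = None,
) -> SwitchingExperiment:
    """Reference repeated-switching experiment: a field of expressing cells.

    The fitted quantity in a repeated-switching assay is the average trace
    over a field of cells, so the reference synthetic experiment simulates
    ``n_objects`` cells with lognormal expression-level scatter and fits
    their mean.  ``truth`` defaults to :func:`default_truth`.
    """
    protocol = SwitchingProtocol.hela_default(n_cycles)
    if truth is None:
        truth = default_truth(seed, noise=noise)
    scales_seed = (int(seed) * 1_000_003 + 7) % 2**31
    scales = np.random.default_rng(scales_seed).lognormal(mean=0.0, sigma=0.3, size=n_objects)
    return simulate_traces(protocol, truth, n_objects=n_objects, intensity_scales=scales)


def _expected_trace(protocol: SwitchingProtocol, truth: GroundTruth) -> np.ndarray:
    """Noiseless per-frame expected fluorescence of one object (unit scale)."""
    kin = truth.kinetics
    n = np.arange(protocol.n_cycles, dtype=float)
    a_n, b_n = population_closed_form(truth.popdyn, n)

    t_off = protocol.off_local_times()
    s_a = kin.species_decay(t_off, "A")
    s_b = kin.species_decay(t_off, "B")

    frames_pc = protocol.frames_per_cycle
    expected = np.empty(protocol.n_frames)
    t_on = np.arange(protocol.on_periods) * protocol.period_duration
    for i in range(protocol.n_cycles):
        start = i * frames_pc
        full = a_n[i] + b_n[i] + kin.c
        off = a_n[i] * s_a + b_n[i] * s_b + kin.c
        if kin.k_on is None:
            on = np.full(protocol.on_periods, full)
        else:
            # finite on-switching: relax from the previous residual level to full
            resid = expected[start - 1] if i > 0 else kin.c
            on = full - (full - resid) * np.exp(-kin.k_on * t_on)
        expected[start : start + protocol.on_periods] = on
        expected[start + protocol.on_periods : start + frames_pc] = off
    if protocol.trailing_on_periods:
        # trailing violet block reads the fully on-switched level of the last cycle
        full = a_n[-1] + b_n[-1] + kin.c
        expected[protocol.n_cycles * frames_pc :] = full
    return expected


def simulate_traces(
    protocol: SwitchingProtocol,
    truth: GroundTruth,
    n_objects: int = 1,
    intensity_scales: np.ndarray | None = None,
) -> SwitchingExperiment:
    """Simulate per-frame fluorescence traces for a full switching experiment.

    Within the off half-cycle of cycle n the expected signal is
    ``a_n * S_A(t) + b_n * S_B(t) + c`` with the species decays from the
    ground-truth kinetics and per-cycle amplitudes from the closed-form
    population dynamics.  Violet half-cycles reset the surviving population
    to the on state (instantaneously unless a finite ``k_on`` is set).  Noise
    is applied per the ground truth's :class:`NoiseModel` with its seeded
    generator, and the full ground truth is embedded in the experiment
    metadata.
    """
    if intensity_scales is not None:
        intensity_scales = np.asarray(intensity_scales, dtype=float)
        if intensity_scales.shape != (n_objects,):
            raise ValueError("intensity_scales must have length n_objects")
        if np.any(~np.isfinite(intensity_scales)) or np.any(intensity_scales <= 0):
            raise ValueError("intensity_scales must be positive and finite")
    else:
        intensity_scales = np.ones(n_objects)
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")

    expected = _expected_trace(protocol, truth)
    rng = np.random.default_rng(truth.seed)
    traces = np.empty((n_objects, protocol.n_frames))
    for j in range(n_objects):
        scaled = intensity_scales[j] * expected
        traces[j] = truth.noise.apply(scaled, rng) if truth.noise.enabled else scaled + truth.noise.background
    return SwitchingExperiment(
        protocol=protocol,
        traces=traces,
        metadata={
            "ground_truth": truth.to_dict(),
            "intensity_scales": intensity_scales.tolist(),
            "protocol": protocol.to_dict(),
        },
    )


def simulate_recovery_trace(
    truth: GroundTruth,
    duration: float = 600.0,
    sampling: float = 30.0,
    k_th: float = 0.002,
    F0: float = 0.1,
    Finf: float = 0.8,
) -> pd.DataFrame:
    """Simulate thermal recovery of off-switched fluorescence.

    Samples F(t) = F_inf - (F_inf - F_0) exp(-k_th t) every ``sampling``
    seconds from t = 0 through ``duration`` inclusive, with noise per the
    ground truth.  Returns a table (time_s, intensity) with the generating
    parameters attached as ``DataFrame.attrs``.
    """
    if not sampling > 0 or duration < sampling:
        raise ValueError("require duration >= sampling > 0")
    if not np.isfinite(k_th) or k_th < 0:
        raise ValueError("thermal recovery rate k_th must be >= 0")
    t = np.arange(0.0, duration + sampling / 2, sampling)
    expected = Finf - (Finf - F0) * np.exp(-k_th * t)
    rng = np.random.default_rng(truth.seed)
    intensity = truth.noise.apply(expected, rng) if truth.noise.enabled else expected
    out = pd.DataFrame({"time_s": t, "intensity": intensity})
    out.attrs["ground_truth"] = {"k_th": k_th, "F0": F0, "Finf": Finf, "seed": int(truth.seed)}
    return out


def simulate_titration(
    pKa: float,
    A_max: float = 1.0,
    hill: float = 1.0,
    pH_grid: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an anionic-peak absorbance pH titration.

    A(pH) = A_max / (1 + 10^(hill (pKa - pH))) + Gaussian noise — the
    Henderson–Hasselbalch sigmoid, monotone increasing in pH for hill > 0.
    Defaults to the pH 3..11 grid in half-unit steps.
    """
    if pH_grid is None:
        pH_grid = np.arange(3.0, 11.0 + 0.25, 0.5)
    pH = np.asarray(pH_grid, dtype=float)
    if pH.size == 0:
        raise ValueError("pH grid must be non-empty")
    A = A_max / (1.0 + 10.0 ** (hill * (pKa - pH)))
    if noise_sigma > 0:
        A = A + np.random.default_rng(seed).normal(0.0, noise_sigma, size=A.shape)
    out = pd.DataFrame({"pH": pH, "absorbance": A})
    out.attrs["ground_truth"] = {"pKa": pKa, "A_max": A_max, "hill": hill, "seed": int(seed)}
    return out


@dataclass(frozen=True)
class ColonyLayout:
    """Disk-shaped objects on a uniform background, for rendering image stacks."""

    image_shape: tuple[int, int]
    objects: tuple = field(default_factory=tuple)  # (center_row, center_col, radius, scale)
    background_level: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        for row, col, radius, scale in self.objects:
            if radius <= 0:
                raise ValueError("disk radii must be positive")
            if not (0 <= row - radius and row + radius < h and 0 <= col - radius and col + radius < w):
                raise ValueError("objects must lie fully within the image bounds")
            if scale <= 0:
                raise ValueError("intensity scales must be positive")

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def masks(self) -> list[np.ndarray]:
        h, w = self.image_shape
        rr, cc = np.mgrid[0:h, 0:w]
        return [
            (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
            for row, col, radius, _ in self.objects
        ]

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "objects": [list(o) for o in self.objects],
            "background_level": self.background_level,
        }


def random_layout(
    n_objects: int,
    image_shape: tuple[int, int] = (256, 256),
    radius_range: tuple[float, float] = (6.0, 12.0),
    intensity_sigma: float = 0.3,
    background_level: float = 0.0,
    seed: int = 0,
    allow_overlap: bool = False,
    max_tries: int = 10_000,
) -> ColonyLayout:
    """Place non-overlapping disks with lognormal intensity scales."""
    rng = np.random.default_rng(seed)
    h, w = image_shape
    placed: list[tuple[float, float, float, float]] = []
    tries = 0
    while len(placed) < n_objects:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place all disks without overlap; enlarge the image")
        r = rng.uniform(*radius_range)
        row = rng.uniform(r + 1, h - r - 2)
        col = rng.uniform(r + 1, w - r - 2)
        if not allow_overlap and any(
            np.hypot(row - pr, col - pc) < r + pr2 + 2 for pr, pc, pr2, _ in placed
        ):
            continue
        scale = float(rng.lognormal(mean=0.0, sigma=intensity_sigma))
        placed.append((float(row), float(col), float(r), scale))
    return ColonyLayout(
        image_shape=image_shape, objects=tuple(placed), background_level=background_level
    )


def render_colony_stack(
    experiment: SwitchingExperiment,
    layout: ColonyLayout,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render an image stack: each frame is background plus per-object disks.

    Every disk is scaled by its object's trace value at that frame (times the
    layout's per-object intensity scale).  Requires exactly one trace per
    layout object.  Returns a float array (n_frames, height, width).
    """
    if experiment.n_objects != layout.n_objects:
        raise ValueError(
            f"{experiment.n_objects} traces but {layout.n_objects} layout objects"
        )
    masks = layout.masks()
    n_frames = experiment.n_frames
    h, w = layout.image_shape
    stack = np.full((n_frames, h, w), float(layout.background_level))
    for mask, (_, _, _, scale), trace in zip(masks, layout.objects, experiment.traces):
        stack[:, mask] += scale * trace[:, None]
    if noise is not None and noise.enabled:
        rng = np.random.default_rng(experiment.metadata.get("ground_truth", {}).get("seed", 0) if seed is None else seed)
        stack = noise.apply(stack, rng)
    return stack
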