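"""Synthetic paired master/slave NIR scenarios with known ground truth.

The generator emulates the standard setting for calibration-transfer
experiments: two spectrometers measure samples of the same chemical
system, with concentrations drawn from a shared range, but the slave
instrument's response differs from the master's by smooth wavelength-
dependent gain and offset curves, an optional fractional wavelength
shift, per-sample multiplicative scatter, and higher noise.

Master physics is a Beer–Lambert linear mixture: pure-component spectra
are sums of Gaussian absorption bands with seeded random centers, widths
and amplitudes; sample spectra are concentration-weighted sums plus a
low-order polynomial baseline and iid Gaussian noise.  Because the
mixture is exactly linear in the analyte concentration, a PLS1 model
with as many latent variables as components recovers it up to noise,
which makes parameter-recovery tests sharp.

Randomness uses :class:`numpy.random.Generator` with the PCG64 bit
generator, so a given seed reproduces a scenario bit-identically across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import SpectraSet

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "generate_scenario",
    "make_affine_slave",
    "measure_on_slave",
]


@dataclass
class ScenarioConfig:
    """Parameters of a paired-instrument scenario.

    Defaults describe a mid-size NIR experiment: 60 calibration and 20
    test samples over 200 channels, three absorbing components of which
    the first is the analyte (reference values in arbitrary
    concentration units over a shared 5–15 range), and an affine
    (gain + offset + scatter) instrument difference of a few percent
    with realistic absorbance noise (~1e-3 AU).  The wavelength shift
    defaults to zero: shifting is the distortion family an affine
    per-component correction does *not* target, and is enabled
    explicitly when probing failure modes.
    """

    n_cal: int = 60
    n_test: int = 20
    p: int = 200
    wl_start: float = 1100.0
    wl_step: float = 2.0
    k_components: int = 3
    peak_count_per_component: int = 4
    concentration_range: tuple[float, float] = (5.0, 15.0)
    gain_amplitude: float = 0.1
    offset_amplitude: float = 0.05
    wavelength_shift: float = 0.0
    scatter_sd: float = 0.01
    noise_sd_master: float = 0.001
    noise_sd_slave: float = 0.002
    baseline_amplitude: float = 0.05
    seed: int = 0
    rng_algorithm: str = field(default="PCG64", repr=False)

    def __post_init__(self) -> None:
        for name in ("n_cal", "n_test", "p", "k_components", "peak_count_per_component"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("scatter_sd", "noise_sd_master", "noise_sd_slave"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.concentration_range
        if not hi > lo:
            raise ValueError("concentration_range must be a nonempty interval")
        if abs(self.wavelength_shift) >= self.p:
            raise ValueError("wavelength_shift must be smaller than channel count")


@dataclass
class SyntheticScenario:
    """Generated datasets plus the ground truth used to build them.

    Slave sets carry their true reference values for *evaluation only*;
    the transfer method itself never sees them.  ``concentrations`` maps
    each dataset name to its full component-concentration matrix and
    ``baseline`` is the shared polynomial baseline, so tests can rebuild
    the noise-free spectra exactly.
    """

    config: ScenarioConfig
    master_cal: SpectraSet
    slave_cal: SpectraSet
    slave_test: SpectraSet
    pure_spectra: np.ndarray
    baseline: np.ndarray
    concentrations: dict
    true_distortion: dict


def _gaussian_band_spectra(rng: np.random.Generator, cfg: ScenarioConfig) -> np.ndarray:
    """Pure-component spectra: sums of Gaussian absorption bands."""
    wl = cfg.wl_start + cfg.wl_step * np.arange(cfg.p)
    span = wl[-1] - wl[0]
    S = np.zeros((cfg.k_components, cfg.p))
    for k in range(cfg.k_components):
        centers = rng.uniform(wl[0], wl[-1], cfg.peak_count_per_component)
        widths = rng.uniform(0.05 * span, 0.2 * span, cfg.peak_count_per_component)
        amps = rng.uniform(0.005, 0.02, cfg.peak_count_per_component)
        for c, w, a in zip(centers, widths, amps):
            S[k] += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return S


def _smooth_curve(rng: np.random.Generator, p: int, n_waves: int = 3) -> np.ndarray:
    """Slowly varying seeded curve on a length-p grid with max |value| = 1."""
    x = np.linspace(0.0, 1.0, p)
    curve = np.zeros(p)
    for _ in range(n_waves):
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        curve += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * freq * x + phase)
    m = np.max(np.abs(curve))
    return curve / m if m > 0 else curve


def _apply_distortion(
    X: np.ndarray,
    gain: np.ndarray,
    offset: np.ndarray,
    wavelength_shift: float,
    scatter_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n, p = X.shape
    out = X * gain + offset
    if wavelength_shift != 0.0:
        idx = np.clip(np.arange(p, dtype=float) + wavelength_shift, 0.0, p - 1.0)
        grid = np.arange(p, dtype=float)
        out = np.vstack([np.interp(idx, grid, row) for row in out])
    if scatter_sd > 0:
        out = out * (1.0 + rng.normal(0.0, scatter_sd, (n, 1)))
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return out


def make_affine_slave(
    master: SpectraSet,
    gain_amplitude: float = 0.1,
    offset_amplitude: float = 0.05,
    wavelength_shift: float = 0.0,
    scatter_sd: float = 0.01,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> SpectraSet:
    """Distort master spectra into slave-instrument spectra.

    Applies, in order: a smooth multiplicative gain curve
    ``g = 1 + gain_amplitude * s1(lambda)``, a smooth additive offset
    ``offset_amplitude * s2(lambda)`` (absorbance units), a fractional
    channel shift by linear interpolation, a per-sample scatter
    multiplier ``1 + N(0, scatter_sd)``, and iid Gaussian noise.  With
    every parameter zero the output equals the input exactly.
    """
    if abs(wavelength_shift) >= master.n_channels:
        raise ValueError("wavelength_shift must be smaller than channel count")
    rng = np.random.default_rng(seed)
    p = master.n_channels
    gain = 1.0 + gain_amplitude * _smooth_curve(rng, p)
    offset = offset_amplitude * _smooth_curve(rng, p)
    out = _apply_distortion(
        master.spectra, gain, offset, wavelength_shift, scatter_sd, noise_sd, rng
    )
    return SpectraSet(
        spectra=out,
        wavelengths=master.wavelengths,
        reference=None if master.reference is None else master.reference.copy(),
        ids=None if master.ids is None else list(master.ids),
    )


def measure_on_slave(
    scenario: "SyntheticScenario", master: SpectraSet, seed: int = 0
) -> SpectraSet:
    """Re-measure master-instrument samples on the scenario's slave.

    Applies the scenario's *stored* gain/offset curves and wavelength
    shift — the same physical slave instrument that produced
    ``slave_cal`` and ``slave_test`` — with fresh scatter and noise
    draws.  This is how paired transfer standards arise: the same
    samples, measured on both instruments.
    """
    cfg = scenario.config
    rng = np.random.default_rng(seed)
    out = _apply_distortion(
        master.spectra,
        scenario.true_distortion["gain"],
        scenario.true_distortion["offset"],
        cfg.wavelength_shift,
        cfg.scatter_sd,
        cfg.noise_sd_slave,
        rng,
    )
    return SpectraSet(
        spectra=out,
        wavelengths=master.wavelengths,
        reference=None if master.reference is None else master.reference.copy(),
        ids=None if master.ids is None else list(master.ids),
    )


def generate_scenario(cfg: ScenarioConfig | None = None) -> SyntheticScenario:
    """Generate a full paired-instrument scenario from a config.

    Master and slave calibration concentrations are independent draws
    from the same distribution (the shared-range assumption).  Both
    slave sets see the *same* smooth gain/offset curves — they come from
    one physical instrument — but independent scatter and noise draws.
    Bit-reproducible per seed.
    """
    cfg = cfg or ScenarioConfig()
    ss = np.random.SeedSequence(cfg.seed)
    (rng_bands, rng_conc, rng_baseline, rng_m, rng_curves,
     rng_scal, rng_stest) = [np.random.default_rng(s) for s in ss.spawn(7)]

    S = _gaussian_band_spectra(rng_bands, cfg)
    wl = cfg.wl_start + cfg.wl_step * np.arange(cfg.p)
    lo, hi = cfg.concentration_range
    C_mcal = rng_conc.uniform(lo, hi, (cfg.n_cal, cfg.k_components))
    C_scal = rng_conc.uniform(lo, hi, (cfg.n_cal, cfg.k_components))
    C_stest = rng_conc.uniform(lo, hi, (cfg.n_test, cfg.k_components))

    x01 = np.linspace(-1.0, 1.0, cfg.p)
    coeffs = rng_baseline.uniform(-1.0, 1.0, 3)
    baseline = cfg.baseline_amplitude * (coeffs[0] + coeffs[1] * x01 + coeffs[2] * x01**2)

    X_mcal = C_mcal @ S + baseline
    if cfg.noise_sd_master > 0:
        X_mcal = X_mcal + rng_m.normal(0.0, cfg.noise_sd_master, X_mcal.shape)

    gain = 1.0 + cfg.gain_amplitude * _smooth_curve(rng_curves, cfg.p)
    offset = cfg.offset_amplitude * _smooth_curve(rng_curves, cfg.p)
    X_scal = _apply_distortion(
        C_scal @ S + baseline, gain, offset, cfg.wavelength_shift,
        cfg.scatter_sd, cfg.noise_sd_slave, rng_scal,
    )
    X_stest = _apply_distortion(
        C_stest @ S + baseline, gain, offset, cfg.wavelength_shift,
        cfg.scatter_sd, cfg.noise_sd_slave, rng_stest,
    )

    return SyntheticScenario(
        config=cfg,
        master_cal=SpectraSet(X_mcal, wl, reference=C_mcal[:, 0]),
        slave_cal=SpectraSet(X_scal, wl, reference=C_scal[:, 0]),
        slave_test=SpectraSet(X_stest, wl, reference=C_stest[:, 0]),
        pure_spectra=S,
        baseline=baseline,
        concentrations={
            "master_cal": C_mcal,
            "slave_cal": C_scal,
            "slave_test": C_stest,
        },
        true_distortion={
            "gain": gain,
            "offset": offset,
            "wavelength_shift": cfg.wavelength_shift,
            "scatter_sd": cfg.scatter_sd,
            "rng_algorithm": cfg.rng_algorithm,
        },
    )
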