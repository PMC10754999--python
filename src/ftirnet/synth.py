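"""Synthetic serum-like FTIR spectra with controllable class separability.

Real mid-infrared serum spectra are dominated by a handful of broad
vibrational bands: the amide A band near 3280 cm^-1 (N-H stretch), the
C-H stretch region near 2940 cm^-1 (fatty acids, cholesterol), amide I at
1641 cm^-1 and amide II at 1542 cm^-1, the proline/tryptophan region near
1420 cm^-1, amide III at 1245 cm^-1 and the carbohydrate region near
1078 cm^-1.  Between disease groups the band *positions* barely move; what
differs is the relative band magnitude.  The generator mirrors exactly that
structure:

    spectrum = sum_b  A_b * s_cb * p_sb * G(w; center_b, sigma_b)
             + quadratic baseline + replicate offset + iid Gaussian noise

where ``A_b`` is the base amplitude of band ``b``, ``s_cb`` the class
multiplier, ``p_sb`` a per-sample log-normal-ish perturbation (biological
variability), and ``G`` a unit-height Gaussian.  Replicates of one sample
share ``p_sb`` and differ only by a small additive offset and the noise
term, so averaging replicates demonstrably improves SNR.

Randomness is hierarchical: every (class, sample) pair and every replicate
gets its own stream spawned from the single config seed, so enlarging the
dataset never reshuffles existing samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .spectra import DEFAULT_CLASSES, SpectralDataset, WavenumberGrid

#: Band centers (cm^-1) of the major serum FTIR features.
DEFAULT_BAND_CENTERS = (3280.0, 2940.0, 1641.0, 1542.0, 1420.0, 1245.0, 1078.0)

#: Gaussian sigma (cm^-1): broad for the amide-A / C-H stretch bands,
#: narrower for the fingerprint region.
DEFAULT_BAND_WIDTHS = (60.0, 60.0, 20.0, 20.0, 20.0, 20.0, 20.0)

#: Base amplitudes (arbitrary absorbance units); amide I strongest.
DEFAULT_BAND_AMPLITUDES = (0.90, 0.45, 1.00, 0.80, 0.30, 0.25, 0.20)

PRESETS = ("easy", "hard", "null")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band."""

    center: float
    width: float
    base_amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0, got {self.width}")
        if self.base_amplitude < 0:
            raise ConfigError(f"band amplitude must be >= 0, got {self.base_amplitude}")


def default_bands() -> tuple:
    return tuple(
        BandSpec(c, w, a)
        for c, w, a in zip(DEFAULT_BAND_CENTERS, DEFAULT_BAND_WIDTHS, DEFAULT_BAND_AMPLITUDES)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic dataset."""

    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    bands: tuple = field(default_factory=default_bands)
    class_names: tuple = DEFAULT_CLASSES
    class_amplitude_scale: tuple = ()  # one multiplier vector per class
    n_samples_per_class: int = 80
    n_replicates: int = 3
    baseline_slope: float = 0.02
    baseline_curvature: float = 0.01
    noise_sd: float = 0.01
    sample_scale_sd: float = 0.03
    replicate_jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 1:
            raise ConfigError("n_samples_per_class must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.replicate_jitter_sd < 0 or self.sample_scale_sd < 0:
            raise ConfigError("noise/jitter/sample-scale SDs must be >= 0")
        if len(self.class_amplitude_scale) != len(self.class_names):
            raise ConfigError(
                f"class_amplitude_scale needs one vector per class "
                f"({len(self.class_names)}), got {len(self.class_amplitude_scale)}"
            )
        for ci, vec in enumerate(self.class_amplitude_scale):
            if len(vec) != len(self.bands):
                raise ConfigError(
                    f"class {self.class_names[ci]!r}: amplitude vector length "
                    f"{len(vec)} != number of bands {len(self.bands)}"
                )
        for b in self.bands:
            if not (self.grid.start <= b.center <= self.grid.stop):
                raise ConfigError(
                    f"band center {b.center} cm^-1 outside grid "
                    f"[{self.grid.start}, {self.grid.stop}]"
                )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {"start": self.grid.start, "stop": self.grid.stop, "step": self.grid.step}
        d["bands"] = [list(b.__dict__.values()) for b in self.bands]
        d["class_names"] = list(self.class_names)
        d["class_amplitude_scale"] = [list(v) for v in self.class_amplitude_scale]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "grid" in d:
            d["grid"] = WavenumberGrid(**d["grid"])
        if "bands" in d:
            d["bands"] = tuple(BandSpec(*b) if not isinstance(b, BandSpec) else b for b in d["bands"])
        for key in ("class_names",):
            if key in d:
                d[key] = tuple(d[key])
        if "class_amplitude_scale" in d:
            d["class_amplitude_scale"] = tuple(tuple(v) for v in d["class_amplitude_scale"])
        return cls(**d)


# ---------------------------------------------------------------------------
# presets

# Class multiplier vectors, one entry per band in DEFAULT_BAND_CENTERS order.
# The patterns are loosely physiological: amide bands reduced in AS, raised
# amide + lipid with lowered proline/tryptophan in RA, raised carbohydrate
# and proline/tryptophan in OA, all ones for healthy controls.  "easy" gives
# multi-band differences of 10-15% against 1% point noise and 3% sample
# variability (Bayes accuracy ~1); "hard" leaves a single-band difference of
# order one noise SD in per-point RMS; "null" removes the signal entirely.
_EASY_SCALES = {
    "AS": (0.85, 0.90, 0.85, 0.85, 0.90, 0.85, 1.00),
    "RA": (1.10, 1.15, 1.10, 1.10, 0.80, 1.10, 1.00),
    "OA": (1.00, 1.00, 1.12, 1.12, 1.30, 1.12, 1.25),
    "HC": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
}
_HARD_SCALES = {
    "AS": (1.00, 1.00, 0.92, 1.00, 1.00, 1.00, 1.00),
    "RA": (1.00, 1.00, 1.08, 1.00, 1.00, 1.00, 1.00),
    "OA": (1.00, 1.00, 1.00, 1.10, 1.00, 1.00, 1.00),
    "HC": (1.00, 1.00, 1.00, 1.00, 1.00, 1.00, 1.00),
}


def preset(name: str, **overrides) -> SynthConfig:
    """Named generator configurations with known separability.

    ``easy``
        Multi-band class differences well clear of the noise; a
        nearest-class-mean rule on the noiseless templates is perfect.
    ``hard``
        Class templates differ by roughly one noise SD per point (RMS);
        classes genuinely overlap.
    ``null``
        Identical multipliers for every class: no signal, any classifier's
        expected accuracy is 1/n_classes.
    """
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESETS}")
    if name == "easy":
        scales = tuple(_EASY_SCALES[c] for c in DEFAULT_CLASSES)
        cfg = SynthConfig(class_amplitude_scale=scales)
    elif name == "hard":
        scales = tuple(_HARD_SCALES[c] for c in DEFAULT_CLASSES)
        cfg = SynthConfig(class_amplitude_scale=scales, sample_scale_sd=0.05)
    else:  # null
        ones = tuple((1.0,) * len(DEFAULT_BAND_CENTERS) for _ in DEFAULT_CLASSES)
        cfg = SynthConfig(class_amplitude_scale=ones)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generation


def class_templates(cfg: SynthConfig) -> np.ndarray:
    """Noiseless class template spectra, shape (n_classes, n_points).

    Template = band sum with class multipliers + baseline; the fixed part of
    every spectrum of that class.
    """
    w = cfg.grid.wavenumbers
    t = (w - cfg.grid.start) / (cfg.grid.stop - cfg.grid.start)
    baseline = cfg.baseline_slope * t + cfg.baseline_curvature * t**2
    shapes = np.stack([np.exp(-0.5 * ((w - b.center) / b.width) ** 2) for b in cfg.bands])
    amps = np.array([b.base_amplitude for b in cfg.bands])
    out = []
    for scales in cfg.class_amplitude_scale:
        out.append((amps * np.asarray(scales)) @ shapes + baseline)
    return np.stack(out)


def template_rms_distances(cfg: SynthConfig) -> np.ndarray:
    """Pairwise per-point RMS distance between class templates (upper triangle)."""
    tpl = class_templates(cfg)
    n = tpl.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = np.sqrt(np.mean((tpl[i] - tpl[j]) ** 2))
    return out


def generate(cfg: SynthConfig) -> SpectralDataset:
    """Generate the labelled replicate-level dataset described by ``cfg``.

    Returns ``n_classes * n_samples_per_class * n_replicates`` spectra; pass
    the result through :func:`ftirnet.spectra.average_replicates` to obtain
    one spectrum per sample.  A pure function of ``cfg`` (seed included).
    """
    w = cfg.grid.wavenumbers
    t = (w - cfg.grid.start) / (cfg.grid.stop - cfg.grid.start)
    baseline = cfg.baseline_slope * t + cfg.baseline_curvature * t**2
    shapes = np.stack([np.exp(-0.5 * ((w - b.center) / b.width) ** 2) for b in cfg.bands])
    amps = np.array([b.base_amplitude for b in cfg.bands])

    rows = []
    spectra = []
    for ci, cname in enumerate(cfg.class_names):
        scales = np.asarray(cfg.class_amplitude_scale[ci], dtype=float)
        for si in range(cfg.n_samples_per_class):
            srng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(ci, si)))
            sample_pert = 1.0 + cfg.sample_scale_sd * srng.standard_normal(len(cfg.bands))
            sample_pert = np.clip(sample_pert, 0.0, None)
            clean = (amps * scales * sample_pert) @ shapes + baseline
            sid = f"{cname}{si:03d}"
            for ri in range(cfg.n_replicates):
                rrng = np.random.default_rng(
                    np.random.SeedSequence(cfg.seed, spawn_key=(ci, si, ri))
                )
                jitter = cfg.replicate_jitter_sd * rrng.standard_normal()
                noise = cfg.noise_sd * rrng.standard_normal(cfg.grid.n_points)
                spectra.append(clean + jitter + noise)
                rows.append({"sample_id": sid, "replicate_id": ri, "class_label": cname})
    return SpectralDataset(
        grid=cfg.grid,
        absorbance=np.vstack(spectra),
        meta=pd.DataFrame(rows),
        class_names=cfg.class_names,
    )
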