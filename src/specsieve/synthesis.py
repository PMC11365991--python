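"""Synthetic FTIR data: pair mixing, SNR-controlled membrane contamination and
a parametric band-model simulator for seed spectra.

Three synthetic datasets drive the pipeline, mirroring how contaminated field
measurements arise:

* synthetic *clean* spectra — weighted sums of two same-class seed spectra,
  emulating replicate-to-replicate variation of a pure polymer;
* synthetic *membrane filter* spectra — the same construction on filter seeds;
* synthetic *noisy* spectra — ``s = y + β·z`` where ``β`` scales the membrane
  contribution; the SNR in dB is ``−20·log10(β)``, so 0 dB means the membrane
  enters at the same amplitude as the polymer and −30 dB means it is ~31.6×
  stronger. Every synthetic spectrum is min-max normalized.

Because the measured seed spectra of the original study are request-only, the
module also simulates seed libraries from parametric band models (sums of
Lorentzian/Gaussian bands with replicate jitter), so the whole pipeline is
testable without any download.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .spectra import (
    SpectraError,
    Spectrum,
    SpectrumSet,
    canonical_grid,
    minmax_normalize,
)

__all__ = [
    "Mixture",
    "Band",
    "BandModel",
    "snr_to_beta",
    "beta_to_snr",
    "mix_pair",
    "make_noisy",
    "synthesize_dataset",
    "synthesize_clean_set",
    "synthesize_membrane_set",
    "split_halves",
    "simulate_seed_library",
    "toy_band_library",
    "polymer_band_library",
    "load_band_models",
    "save_band_models",
    "MEMBRANE_LABEL",
]

MEMBRANE_LABEL = "membrane_filter"


class SynthesisError(SpectraError):
    """Raised for invalid mixing or simulation requests."""


@dataclass(frozen=True)
class Mixture:
    """A synthetic noisy spectrum with its ground truth.

    ``noisy`` is the min-max normalized ``y + β·z``; ``clean_truth`` is the
    uncontaminated polymer spectrum the denoiser should recover.
    """

    noisy: Spectrum
    clean_truth: Spectrum
    membrane: Spectrum
    beta: float
    snr_db: float
    label: str

    def __post_init__(self) -> None:
        if abs(self.snr_db - beta_to_snr(self.beta)) > 1e-9:
            raise SynthesisError("snr_db and beta are inconsistent")
        if not self.noisy.is_normalized:
            raise SynthesisError("noisy spectrum must be min-max normalized")
        if self.clean_truth.label != self.label:
            raise SynthesisError("clean_truth label must match the mixture label")


def snr_to_beta(snr_db: float) -> float:
    """Membrane amplitude scale β for a commanded SNR: β = 10^(−SNR/20)."""
    return 10.0 ** (-snr_db / 20.0)


def beta_to_snr(beta: float) -> float:
    """Inverse of :func:`snr_to_beta`: SNR(dB) = −20·log10(β)."""
    if beta <= 0:
        raise SynthesisError("beta must be positive")
    return -20.0 * math.log10(beta)


def mix_pair(a: Spectrum, b: Spectrum, w: float) -> Spectrum:
    """Normalized weighted sum ``w·a + (1−w)·b`` of two same-class spectra."""
    if a.label != b.label:
        raise SynthesisError(f"label mismatch: {a.label!r} vs {b.label!r}")
    if not np.array_equal(a.wavenumbers, b.wavenumbers):
        raise SynthesisError("cannot mix spectra on different grids")
    if not (0.0 <= w <= 1.0):
        raise SynthesisError("mixing weight must lie in [0, 1]")
    if not (a.is_normalized and b.is_normalized):
        raise SynthesisError("mix_pair expects min-max normalized inputs")
    mixed = a.with_intensities(w * a.intensities + (1.0 - w) * b.intensities)
    return minmax_normalize(mixed)


def make_noisy(y: Spectrum, z: Spectrum, snr_db: float) -> Mixture:
    """Contaminate a clean spectrum with a membrane spectrum at a commanded SNR."""
    if not np.array_equal(y.wavenumbers, z.wavenumbers):
        raise SynthesisError("clean and membrane spectra must share a grid")
    if y.label is None:
        raise SynthesisError("clean spectrum must carry a class label")
    if not (y.is_normalized and z.is_normalized):
        raise SynthesisError("make_noisy expects min-max normalized inputs")
    beta = snr_to_beta(snr_db)
    noisy = minmax_normalize(
        y.with_intensities(y.intensities + beta * z.intensities)
    )
    return Mixture(
        noisy=noisy,
        clean_truth=y,
        membrane=z,
        beta=beta,
        snr_db=-20.0 * math.log10(beta),
        label=y.label,
    )


def _sorted_seeds(seeds: Sequence[Spectrum]) -> list[Spectrum]:
    # content-sorted so results do not depend on file order
    return sorted(seeds, key=lambda s: s.intensities.tobytes())


def _random_pair_mix(
    pool: list[Spectrum], rng: np.random.Generator
) -> Spectrum:
    i, j = rng.choice(len(pool), size=2, replace=False)
    w = rng.uniform(0.0, 1.0)
    return mix_pair(pool[int(i)], pool[int(j)], float(w))


def synthesize_clean_set(
    seeds: SpectrumSet, n_per_class: int, rng_seed: int
) -> SpectrumSet:
    """Synthetic clean spectra: ``n_per_class`` pair-mixes per non-membrane class."""
    rng = np.random.default_rng(rng_seed)
    out: list[Spectrum] = []
    for label in sorted(c for c in seeds.class_names if c != MEMBRANE_LABEL):
        pool = _sorted_seeds(seeds.by_label(label))
        if len(pool) < 2:
            raise SynthesisError(f"class {label!r} needs ≥2 seed spectra")
        out.extend(_random_pair_mix(pool, rng) for _ in range(n_per_class))
    return SpectrumSet(out)


def synthesize_membrane_set(
    seeds: SpectrumSet, n: int, rng_seed: int
) -> SpectrumSet:
    """``n`` synthetic membrane spectra by seeded pair mixing of membrane seeds."""
    pool = _sorted_seeds(
        seeds.by_label(MEMBRANE_LABEL) or list(seeds)
    )
    if len(pool) < 2:
        raise SynthesisError("need ≥2 membrane_filter seed spectra")
    rng = np.random.default_rng(rng_seed)
    return SpectrumSet([_random_pair_mix(pool, rng) for _ in range(n)])


def synthesize_dataset(
    seeds: SpectrumSet, n_per_class: int, snr_db: float, rng_seed: int
) -> list[Mixture]:
    """Synthetic noisy dataset: ``n_per_class`` mixtures per polymer class.

    Each clean component mixes two distinct same-class seeds with a uniform
    weight; each membrane component likewise mixes two membrane seeds; the two
    are combined at the commanded SNR. Selection runs over content-sorted seed
    lists so the output depends only on ``rng_seed``, not on input ordering.
    """
    rng = np.random.default_rng(rng_seed)
    classes = sorted(c for c in seeds.class_names if c != MEMBRANE_LABEL)
    if not classes:
        raise SynthesisError("no polymer classes among the seeds")
    membrane_pool = _sorted_seeds(seeds.by_label(MEMBRANE_LABEL))
    if len(membrane_pool) < 2:
        raise SynthesisError("need ≥2 membrane_filter seed spectra")
    mixtures: list[Mixture] = []
    for label in classes:
        pool = _sorted_seeds(seeds.by_label(label))
        if len(pool) < 2:
            raise SynthesisError(f"class {label!r} needs ≥2 seed spectra")
        for _ in range(n_per_class):
            y = _random_pair_mix(pool, rng)
            z = _random_pair_mix(membrane_pool, rng)
            mixtures.append(make_noisy(y, z, snr_db))
    return mixtures


def split_halves(
    sset: SpectrumSet, rng_seed: int
) -> tuple[SpectrumSet, SpectrumSet]:
    """Random per-class partition into two disjoint halves (train/evaluation).

    Odd class counts place the extra spectrum in the first half.
    """
    rng = np.random.default_rng(rng_seed)
    first: list[Spectrum] = []
    second: list[Spectrum] = []
    labels = sorted(sset.class_names)
    for label in labels:
        members = sset.by_label(label)
        if len(members) < 2:
            raise SynthesisError(f"class {label!r} has <2 spectra; cannot split")
        order = rng.permutation(len(members))
        cut = (len(members) + 1) // 2
        first.extend(members[int(i)] for i in order[:cut])
        second.extend(members[int(i)] for i in order[cut:])
    return SpectrumSet(first), SpectrumSet(second)


# ---------------------------------------------------------------------------
# Parametric band-model simulator


@dataclass(frozen=True)
class Band:
    """One absorption band: center (cm⁻¹), half-width scale (cm⁻¹), height, shape."""

    center: float
    width: float
    height: float
    shape: Literal["gaussian", "lorentzian"] = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise SynthesisError("band width must be > 0")
        if not (0.0 < self.height <= 1.0):
            raise SynthesisError("band height must lie in (0, 1]")
        if self.shape not in {"gaussian", "lorentzian"}:
            raise SynthesisError(f"unknown band shape {self.shape!r}")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        d = grid - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-(d * d) / (2.0 * self.width**2))
        return self.height * self.width**2 / (d * d + self.width**2)


@dataclass(frozen=True)
class BandModel:
    """Parametric description of one material's FTIR band pattern.

    ``jitter`` holds relative perturbation scales applied per replicate to the
    band centers, widths and heights (1-sigma, as fractions of the nominal
    value). ``baseline_amplitude`` bounds a smooth broad-Gaussian baseline.
    """

    class_name: str
    bands: tuple[Band, ...]
    jitter: dict = field(
        default_factory=lambda: {"center": 0.002, "width": 0.05, "height": 0.10}
    )
    baseline_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise SynthesisError(f"model {self.class_name!r} has no bands")
        if self.baseline_amplitude < 0:
            raise SynthesisError("baseline_amplitude must be ≥ 0")
        object.__setattr__(self, "bands", tuple(self.bands))


def _check_centers(model: BandModel, grid: np.ndarray) -> None:
    lo, hi = float(grid[0]), float(grid[-1])
    for band in model.bands:
        if not (lo <= band.center <= hi):
            raise SynthesisError(
                f"model {model.class_name!r}: band center {band.center:g} cm⁻¹ "
                f"outside grid range [{lo:g}, {hi:g}]"
            )


def simulate_seed_library(
    models: Sequence[BandModel],
    replicates_per_class: int,
    rng_seed: int,
    grid: np.ndarray | None = None,
) -> SpectrumSet:
    """Simulate normalized seed spectra from band models.

    Each replicate sums the model's bands with jittered centers/widths/heights
    plus a smooth low-amplitude baseline, then is min-max normalized. With zero
    jitter and zero baseline all replicates of a class are identical.
    """
    if not models:
        raise SynthesisError("no band models given")
    if replicates_per_class < 1:
        raise SynthesisError("replicates_per_class must be ≥ 1")
    grid = canonical_grid() if grid is None else np.asarray(grid, dtype=float)
    for m in models:
        _check_centers(m, grid)
    rng = np.random.default_rng(rng_seed)
    span = float(grid[-1] - grid[0])
    out: list[Spectrum] = []
    for model in models:
        jc = float(model.jitter.get("center", 0.0))
        jw = float(model.jitter.get("width", 0.0))
        jh = float(model.jitter.get("height", 0.0))
        for r in range(replicates_per_class):
            total = np.zeros_like(grid)
            for band in model.bands:
                c = band.center * (1.0 + jc * rng.standard_normal())
                w = band.width * abs(1.0 + jw * rng.standard_normal())
                h = band.height * abs(1.0 + jh * rng.standard_normal())
                total += Band(
                    c, max(w, 1e-6), min(max(h, 1e-6), 1.0), band.shape
                ).evaluate(grid)
            if model.baseline_amplitude > 0:
                amp = rng.uniform(0.0, model.baseline_amplitude)
                center = rng.uniform(grid[0], grid[-1])
                total += amp * np.exp(
                    -((grid - center) ** 2) / (2.0 * (0.5 * span) ** 2)
                )
            spectrum = minmax_normalize(
                Spectrum(grid, total, model.class_name, {"replicate": r})
            )
            out.append(spectrum)
    return SpectrumSet(out)


#: Replicate jitter of the simulated membrane filter: a manufactured filter
#: is far more reproducible than ground polymer samples, so its scales sit
#: well below the class defaults.
MEMBRANE_JITTER = {"center": 0.001, "width": 0.03, "height": 0.04}

#: Replicate jitter of simulated polymer samples (1-sigma, relative).
CLASS_JITTER = {"center": 0.002, "width": 0.05, "height": 0.10}


def toy_band_library(
    n_classes: int = 5,
    n_bands_per_class: int = 3,
    width: float = 10.0,
    shape: Literal["gaussian", "lorentzian"] = "gaussian",
    satellite_offset: float = 22.0,
    satellite_height: float = 0.35,
    jitter: dict | None = None,
    baseline_amplitude: float = 0.0,
) -> list[BandModel]:
    """Separable toy library on the reduced 650–1650 cm⁻¹ grid.

    Band slots are spaced 50 cm⁻¹ apart (well beyond 3× the default width);
    the membrane filter takes three main slots of its own and every class
    takes disjoint slots, so all band *centers* are distinct and class-class
    subspaces are essentially orthogonal (Gaussian bands by default — their
    tails vanish within a slot spacing).

    The membrane model additionally carries one weak narrow *satellite* band
    offset ``satellite_offset`` cm⁻¹ from each class's main band (heights
    decaying geometrically from ``satellite_height``). This mirrors how a
    real cellulose filter's bands crowd the fingerprint region and partially
    coincide with polymer bands: a correlation-matching classifier applied to
    the raw contaminated spectrum is progressively misled as the membrane
    amplitude grows, while the learned membrane atoms absorb the satellites
    and removal restores the polymer signal. Without this partial spectral
    overlap the raw-spectrum baseline would be artificially immune to the
    membrane (gradient correlation is scale-invariant, so a membrane exactly
    orthogonal to every reference cannot change the class ranking at any
    amplitude).
    """
    jitter = jitter if jitter is not None else dict(CLASS_JITTER)
    slots = [690.0 + 50.0 * i for i in range(19)]  # 690 .. 1590
    membrane_slots = [slots[2], slots[9], slots[15]]  # 790, 1140, 1440
    free = [c for c in slots if c not in membrane_slots]
    needed = n_classes * n_bands_per_class
    if needed > len(free):
        raise SynthesisError(
            f"toy library supports at most {len(free) // n_bands_per_class} "
            f"classes with {n_bands_per_class} bands each"
        )
    class_centers = [
        free[b * n_bands_per_class : (b + 1) * n_bands_per_class]
        for b in range(n_classes)
    ]
    mem_bands = [
        Band(c, width, h, shape)
        for c, h in zip(membrane_slots, (1.0, 0.75, 0.5))
    ]
    for b in range(n_classes):
        mem_bands.append(
            Band(
                class_centers[b][0] + satellite_offset,
                width,
                satellite_height * 0.8**b,
                shape,
            )
        )
    models = [
        BandModel(
            MEMBRANE_LABEL,
            tuple(mem_bands),
            jitter=dict(MEMBRANE_JITTER),
            baseline_amplitude=baseline_amplitude,
        )
    ]
    heights = [1.0, 0.7, 0.45][:n_bands_per_class]
    for b in range(n_classes):
        models.append(
            BandModel(
                f"polymer_{chr(ord('A') + b)}",
                tuple(
                    Band(c, width, h, shape)
                    for c, h in zip(class_centers[b], heights)
                ),
                jitter=jitter,
                baseline_amplitude=baseline_amplitude,
            )
        )
    return models


def polymer_band_library() -> list[BandModel]:
    """A small full-range demo library with polymer-inspired band patterns.

    Band positions loosely follow textbook assignments (C–H stretches near
    2850–2960, carbonyl near 1730, C–F near 1150–1210, aromatic ring modes,
    cellulose O–H/C–O for the membrane filter). Intended for examples on the
    canonical grid, not as a spectral reference library.
    """
    L = "lorentzian"
    return [
        BandModel(
            MEMBRANE_LABEL,  # cellulose-like filter
            (
                Band(1030, 25, 1.0, L),
                Band(1160, 20, 0.55, L),
                Band(2900, 30, 0.25, L),
                Band(3340, 120, 0.35, "gaussian"),
            ),
        ),
        BandModel(
            "HDPE",
            (Band(2849, 12, 0.9, L), Band(2917, 12, 1.0, L), Band(1463, 10, 0.3, L), Band(719, 8, 0.2, L)),
        ),
        BandModel(
            "PMMA",
            (Band(1730, 14, 1.0, L), Band(1145, 18, 0.8, L), Band(2951, 14, 0.4, L), Band(1435, 12, 0.35, L)),
        ),
        BandModel(
            "PS",
            (Band(698, 8, 1.0, L), Band(756, 8, 0.6, L), Band(1493, 10, 0.4, L), Band(3026, 12, 0.35, L)),
        ),
        BandModel(
            "PTFE",
            (Band(1203, 16, 1.0, L), Band(1146, 14, 0.9, L)),
        ),
        BandModel(
            "PET",
            (Band(1714, 14, 1.0, L), Band(1241, 16, 0.85, L), Band(1095, 14, 0.6, L), Band(725, 10, 0.5, L)),
        ),
        BandModel(
            "PVC",
            (Band(1427, 12, 0.6, L), Band(1254, 12, 0.7, L), Band(2912, 14, 0.5, L), Band(690, 14, 1.0, L)),
        ),
    ]


# ---------------------------------------------------------------------------
# Band-model config files (YAML or JSON)


def _band_to_dict(b: Band) -> dict:
    return {"center": b.center, "width": b.width, "height": b.height, "shape": b.shape}


def save_band_models(models: Sequence[BandModel], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "class": m.class_name,
            "bands": [_band_to_dict(b) for b in m.bands],
            "jitter": dict(m.jitter),
            "baseline_amplitude": m.baseline_amplitude,
        }
        for m in models
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def load_band_models(path: str | Path) -> list[BandModel]:
    """Load band models from a YAML/JSON list of {class, bands, jitter, ...}."""
    path = Path(path)
    text = path.read_text()
    payload = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(payload, list):
        raise SynthesisError(f"{path}: expected a list of band models")
    models = []
    for entry in payload:
        bands = tuple(
            Band(
                float(b["center"]),
                float(b["width"]),
                float(b["height"]),
                b.get("shape", "lorentzian"),
            )
            for b in entry["bands"]
        )
        models.append(
            BandModel(
                entry["class"],
                bands,
                jitter=dict(entry.get("jitter", {})),
                baseline_amplitude=float(entry.get("baseline_amplitude", 0.0)),
            )
        )
    return models
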