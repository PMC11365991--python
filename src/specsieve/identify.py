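"""Polymer identification by spectral-gradient Pearson correlation.

A spectrum's *gradient* is its first-difference sequence on the uniform
wavenumber grid; it captures band shape while discarding offsets. Two spectra
are compared by the Pearson correlation ρ of their gradients, which is
invariant under positive affine transforms of either spectrum — so raw and
normalized spectra score identically. A query is assigned the class of the
reference spectrum with the maximum ρ. Applied to the raw contaminated
spectrum this is the no-preprocessing baseline; applied to the
dictionary-denoised reconstruction it is the full method.

Note: ρ is a Pearson correlation and can be negative; it is reported as-is
(never clamped) and a negative match simply never wins the argmax against a
positive one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraError, Spectrum, SpectrumSet

__all__ = [
    "ClassificationResult",
    "spectral_gradient",
    "gradient_correlation",
    "classify",
    "classify_baseline",
]


class IdentificationError(SpectraError):
    """Raised for invalid gradient or classification requests."""


@dataclass(frozen=True)
class ClassificationResult:
    """Per-class best gradient correlations and the argmax prediction."""

    per_class_rho: dict
    predicted: str
    matched_reference: str

    def runner_up(self) -> tuple[str, float] | None:
        """Second-best class and its ρ, or None with a single class."""
        ranked = sorted(
            self.per_class_rho.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return ranked[1] if len(ranked) > 1 else None


def spectral_gradient(s: Spectrum) -> np.ndarray:
    """First differences g_n = x_{n+1} − x_n (length N−1) on a uniform grid."""
    steps = np.diff(s.wavenumbers)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
        raise IdentificationError(
            "spectral gradient requires a uniform wavenumber grid; resample first"
        )
    return np.diff(s.intensities)


def gradient_correlation(a: Spectrum, b: Spectrum) -> float:
    """Pearson correlation of the two spectra's gradient sequences."""
    if not np.array_equal(a.wavenumbers, b.wavenumbers):
        raise IdentificationError("spectra must share a wavenumber grid")
    ga = spectral_gradient(a)
    gb = spectral_gradient(b)
    ga = ga - ga.mean()
    gb = gb - gb.mean()
    na = float(np.linalg.norm(ga))
    nb = float(np.linalg.norm(gb))
    if na == 0.0 or nb == 0.0:
        raise IdentificationError(
            "gradient correlation undefined: a spectrum has constant gradient"
        )
    return float(np.clip(ga @ gb / (na * nb), -1.0, 1.0))


def classify(s: Spectrum, references: SpectrumSet) -> ClassificationResult:
    """Assign the class of the reference with the maximum gradient correlation.

    ``per_class_rho`` keeps each class's best ρ; ties in the final argmax go
    to the lexicographically smallest class name.
    """
    if len(references) == 0:
        raise IdentificationError("empty reference set")
    per_class: dict[str, float] = {}
    matched: dict[str, str] = {}
    for i, ref in enumerate(references):
        if ref.label is None:
            raise IdentificationError(f"reference {i} has no class label")
        rho = gradient_correlation(s, ref)
        if ref.label not in per_class or rho > per_class[ref.label]:
            per_class[ref.label] = rho
            matched[ref.label] = ref.meta.get("spectrum_id", f"ref{i}")
    predicted = min(per_class, key=lambda c: (-per_class[c], c))
    return ClassificationResult(
        per_class_rho=per_class,
        predicted=predicted,
        matched_reference=matched[predicted],
    )


def classify_baseline(
    s_noisy: Spectrum, references: SpectrumSet
) -> ClassificationResult:
    """No-preprocessing baseline: classify the raw contaminated spectrum."""
    return classify(s_noisy, references)
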