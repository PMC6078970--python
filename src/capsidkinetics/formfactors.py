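"""Closed-form particle form factors P(q), normalized to P(0) = 1.

Lengths are in angstroms and q in inverse angstroms.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "sphere_form_factor",
    "core_shell_form_factor",
    "gaussian_chain_form_factor",
    "smeared_shell_form_factor",
]


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """3 (sin x - x cos x) / x^3, with the x -> 0 limit handled."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    out[small] = 1.0 - x[small] ** 2 / 10.0
    return out


def sphere_form_factor(q, radius: float) -> np.ndarray:
    """Homogeneous sphere: P(q) = [3 (sin x - x cos x) / x^3]^2, x = qR."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q must be non-negative")
    if radius <= 0:
        raise ValidationError("radius must be positive")
    return _sphere_amplitude(q * radius) ** 2


def core_shell_form_factor(
    q, r_in: float, r_out: float, contrast_ratio: float = 0.0
) -> np.ndarray:
    """Spherical shell with a core of relative contrast ``contrast_ratio``.

    ``contrast_ratio`` is the core-to-shell scattering-length-density
    ratio; 0 gives a hollow shell.  The amplitude is the volume-weighted
    two-radius difference form, normalized so that P(0) = 1.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q must be non-negative")
    if not 0 < r_in < r_out:
        raise ValidationError("need 0 < r_in < r_out")
    v_in = r_in**3
    v_out = r_out**3
    f_in = _sphere_amplitude(q * r_in)
    f_out = _sphere_amplitude(q * r_out)
    num = v_out * f_out - v_in * f_in + contrast_ratio * v_in * f_in
    den = v_out - v_in + contrast_ratio * v_in
    if den == 0:
        raise ValidationError("contrast ratio cancels the particle volume")
    return (num / den) ** 2


def gaussian_chain_form_factor(q, rg: float) -> np.ndarray:
    """Debye function for a Gaussian chain of radius of gyration ``rg``."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q must be non-negative")
    if rg <= 0:
        raise ValidationError("rg must be positive")
    x = (q * rg) ** 2
    out = np.empty_like(x)
    small = x < 1e-4
    xs = x[~small]
    out[~small] = 2.0 * (np.exp(-xs) - 1.0 + xs) / xs**2
    out[small] = 1.0 - x[small] / 3.0 + x[small] ** 2 / 12.0
    return out


def smeared_shell_form_factor(
    q, r_in: float, r_out: float, fuzz: float, contrast_ratio: float = 0.0
) -> np.ndarray:
    """Core-shell form factor with a Gaussian-graded interface.

    The amplitude is multiplied by ``exp(-q^2 fuzz^2 / 2)``, washing out
    the oscillations of the sharp shell (a standard fuzzy-interface
    approximation).  ``fuzz`` is the interface width in angstroms.
    """
    if fuzz < 0:
        raise ValidationError("fuzz must be non-negative")
    q = np.asarray(q, dtype=float)
    damp = np.exp(-(q**2) * fuzz**2 / 2.0)
    return core_shell_form_factor(q, r_in, r_out, contrast_ratio) * damp**2
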