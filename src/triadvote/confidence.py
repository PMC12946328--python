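"""Signed confidence encoding on the probability and log-odds scales.

A participant answers a binary question by picking one of two options and
reporting a confidence between 50% (no preference) and 100% (certainty).
For modelling, the pair (choice, confidence) is folded into a single signed
probability ``c`` directed toward a canonical option, and then mapped to
log-odds ``C = ln(c / (1 - c))``: ``c = 0.5`` (no preference) maps to
``C = 0``, and confidence toward the non-canonical option yields negative
``C``.  Ratings of 100% are truncated to 99% before the transform so the
log-odds stay finite; the magnitude of ``C`` is therefore capped at
``ln(99) ~= 4.60``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "LOG_ODDS_BOUND",
    "OPTIONS",
    "ConfidenceReport",
    "SignedConfidence",
    "encode_signed",
    "encode_percent",
    "decode_percent",
    "from_log_odds",
    "to_log_odds",
    "truncate_extreme",
]

#: Maximum magnitude of a truncated log-odds confidence, ln(0.99/0.01).
LOG_ODDS_BOUND: float = float(np.log(99.0))

#: The two admissible answer labels for a binary question.
OPTIONS = ("option1", "option2")


class InvalidReportError(ValueError):
    """A confidence report violates the 50-100% scale or the option labels."""


@dataclass(frozen=True)
class ConfidenceReport:
    """A raw binary answer: chosen option plus a percent confidence.

    Parameters
    ----------
    choice : str
        One of ``"option1"`` or ``"option2"``.
    confidence_pct : float
        Confidence in the chosen option, on the 50-100 percent scale.
    """

    choice: str
    confidence_pct: float

    def __post_init__(self) -> None:
        if self.choice not in OPTIONS:
            raise InvalidReportError(f"choice must be one of {OPTIONS}, got {self.choice!r}")
        if not 50.0 <= self.confidence_pct <= 100.0:
            raise InvalidReportError(
                f"confidence_pct must lie in [50, 100], got {self.confidence_pct!r}"
            )


@dataclass(frozen=True)
class SignedConfidence:
    """A confidence directed toward a canonical option.

    Attributes
    ----------
    c : float
        Probability-scale confidence in the canonical option, in (0, 1).
    C : float
        Log-odds ``ln(c / (1 - c))``; bounded by ``LOG_ODDS_BOUND`` in
        magnitude after truncation.
    """

    c: float
    C: float


def truncate_extreme(confidence_pct):
    """Truncate extreme ratings to 99% so log-odds stay finite.

    100% maps to 99% (and any fractional rating above 99% is capped at 99%,
    keeping the log-odds magnitude at most ln(99) for every valid report);
    values of 99% or below pass through unchanged.  Raises
    :class:`InvalidReportError` for values outside [50, 100].
    """
    pct = np.asarray(confidence_pct, dtype=float)
    if np.any(pct < 50.0) or np.any(pct > 100.0):
        raise InvalidReportError("confidence_pct must lie in [50, 100]")
    out = np.minimum(pct, 99.0)
    if np.isscalar(confidence_pct) or out.ndim == 0:
        return float(out)
    return out


def to_log_odds(c):
    """Map probability-scale confidence ``c`` in (0, 1) to log-odds."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0.0) or np.any(c_arr >= 1.0):
        raise ValueError("c must lie strictly inside (0, 1); truncate 100% ratings first")
    out = logit(c_arr)
    return float(out) if out.ndim == 0 else out


def from_log_odds(C):
    """Inverse of :func:`to_log_odds`: map log-odds back to (0, 1)."""
    out = expit(np.asarray(C, dtype=float))
    return float(out) if out.ndim == 0 else out


def encode_signed(report: ConfidenceReport, canonical: str = "option1") -> SignedConfidence:
    """Encode a report as a signed confidence toward ``canonical``.

    The reported percent is truncated (100 -> 99), scaled to a probability,
    and reflected about 0.5 when the choice is the non-canonical option, so
    ``c > 0.5`` always means preference for the canonical option.
    """
    if canonical not in OPTIONS:
        raise InvalidReportError(f"canonical must be one of {OPTIONS}, got {canonical!r}")
    pct = truncate_extreme(report.confidence_pct)
    c = pct / 100.0
    if report.choice != canonical:
        c = 1.0 - c
    return SignedConfidence(c=c, C=to_log_odds(c))


def encode_percent(choice, confidence_pct, canonical: str = "option1"):
    """Vectorised percent-scale encoding to signed log-odds.

    Parameters
    ----------
    choice : array-like of str
        Chosen option per report.
    confidence_pct : array-like of float
        Percent confidence per report, in [50, 100].

    Returns
    -------
    ndarray
        Signed log-odds, positive toward ``canonical``.
    """
    pct = truncate_extreme(np.asarray(confidence_pct, dtype=float))
    c = np.asarray(pct, dtype=float) / 100.0
    flip = np.asarray(choice) != canonical
    c = np.where(flip, 1.0 - c, c)
    return logit(c)


def decode_percent(C, canonical: str = "option1", rounded: bool = True):
    """Render signed log-odds back to (choice, percent) reports.

    The sign picks the option (``C >= 0`` -> canonical; the tie ``C = 0``
    deterministically resolves to the canonical option at 50%), and the
    magnitude maps back through the inverse log-odds transform.  With
    ``rounded=True`` percents are rounded to whole numbers and clipped to
    [50, 99], mirroring a percent-entry interface.

    Returns
    -------
    (choices, pct) : tuple of ndarray
    """
    C_arr = np.atleast_1d(np.asarray(C, dtype=float))
    other = OPTIONS[0] if canonical == OPTIONS[1] else OPTIONS[1]
    choices = np.where(C_arr >= 0.0, canonical, other)
    pct = 100.0 * expit(np.abs(C_arr))
    if rounded:
        pct = np.clip(np.round(pct), 50.0, 99.0)
    return choices, pct
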