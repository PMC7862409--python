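"""Six-Port baseband combination and arctangent phase demodulation.

The Six-Port interferometer superimposes the reference and the received
24 GHz signal under four static phase shifts; after power detection the four
baseband channels B3..B6 form two differential pairs that are the quadrature
components of a complex signal

    Z = I + jQ = (B5 - B6) + j(B3 - B4).

The relative chest displacement follows from the unwrapped argument of Z:

    x = phi / (2*pi) * lambda / 2,   phi = unwrap(arg Z),

since a path-length change of lambda/2 produces a full 2*pi phase rotation
(the wave travels to the target and back).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, LowSignalError
from .types import BasebandRecord, DisplacementSignal, IQSignal

#: Fraction of the median |Z| below which a sample's phase is held from the
#: previous sample instead of being evaluated.
MAGNITUDE_FLOOR_FRACTION = 1e-6

#: Default fraction of rail-saturated samples above which a channel is
#: considered clipped. Chosen small: clipping invalidates phase demodulation,
#: so the pipeline must flag rather than silently process.
CLIP_FRACTION_THRESHOLD = 0.01


def combine_baseband(rec: BasebandRecord, remove_dc: bool = False) -> IQSignal:
    """Combine the four detector channels into the complex baseband pair.

    Parameters
    ----------
    rec:
        Four-channel baseband record (equal-length channels enforced by the
        container).
    remove_dc:
        Subtract each channel's mean before differencing. Ideal differential
        pairs cancel detector offsets exactly; real recordings may not, so
        file-based inputs typically enable this.
    """
    b3, b4, b5, b6 = rec.b3, rec.b4, rec.b5, rec.b6
    if remove_dc:
        b3, b4, b5, b6 = (c - c.mean() for c in (b3, b4, b5, b6))
    return IQSignal(i=b5 - b6, q=b3 - b4, fs=rec.fs)


def demodulate_phase(iq: IQSignal, wavelength: float) -> DisplacementSignal:
    """Recover relative displacement from the unwrapped argument of Z.

    Samples whose magnitude |Z| falls below ``MAGNITUDE_FLOOR_FRACTION`` of
    the record median hold the previous sample's phase (the argument of a
    near-zero complex number is noise). If more than half of the record is
    below the floor, demodulation is refused.
    """
    z = iq.z
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("I/Q signal contains non-finite samples")
    if len(z) == 0:
        raise InvalidInputError("empty I/Q signal")
    mag = np.abs(z)
    floor = MAGNITUDE_FLOOR_FRACTION * np.median(mag)
    weak = mag <= floor  # <=: an all-zero record is entirely weak
    if weak.mean() > 0.5:
        raise LowSignalError(
            f"{weak.mean():.0%} of samples below the magnitude floor; "
            "baseband signal too weak for phase demodulation"
        )
    phase = np.angle(z)
    if np.any(weak):
        # Hold phase from the previous strong sample (forward fill; a weak
        # leading run takes the first strong sample's phase).
        idx = np.arange(len(phase))
        strong = ~weak
        if not strong[0]:
            first = np.argmax(strong)
            phase[:first] = phase[first]
            strong[:first] = True
        fill = np.maximum.accumulate(np.where(strong, idx, 0))
        phase = phase[fill]
    phi = np.unwrap(phase)
    x = phi / (2.0 * np.pi) * wavelength / 2.0
    x = x - x[0]
    return DisplacementSignal(x=x, fs=iq.fs, wavelength=wavelength)


def demodulate(rec: BasebandRecord, wavelength: float,
               remove_dc: bool = False) -> DisplacementSignal:
    """Convenience chain: :func:`combine_baseband` then :func:`demodulate_phase`."""
    return demodulate_phase(combine_baseband(rec, remove_dc=remove_dc), wavelength)


@dataclass
class ClippingReport:
    """Per-channel rail-saturation fractions and the overall flag."""

    fractions: dict[str, float]
    flagged: bool
    threshold: float

    @property
    def worst_fraction(self) -> float:
        return max(self.fractions.values())


def detect_clipping(rec: BasebandRecord,
                    rail_fraction_threshold: float = CLIP_FRACTION_THRESHOLD,
                    ) -> ClippingReport:
    """Report the fraction of samples sitting exactly on the rails per channel.

    Rails are the record's ``clip_low``/``clip_high`` metadata when present,
    otherwise estimated as each channel's min/max plateau. A clipped channel
    dwells on the rail for many consecutive samples, so saturation is counted
    as exact (within a tiny absolute epsilon) equality with the rail value; a
    clean sinusoid touches its extremes only instantaneously and reports a
    near-zero fraction. A constant channel is degenerate and reports 1.0.
    """
    fractions: dict[str, float] = {}
    for name, ch in rec.channels().items():
        if len(ch) == 0:
            fractions[name] = 0.0
            continue
        lo = rec.clip_low if rec.clip_low is not None else ch.min()
        hi = rec.clip_high if rec.clip_high is not None else ch.max()
        eps = max(1e-12, 1e-9 * max(abs(lo), abs(hi), 1.0))
        at_rail = (np.abs(ch - lo) <= eps) | (np.abs(ch - hi) <= eps)
        fractions[name] = float(at_rail.mean())
    flagged = any(f > rail_fraction_threshold for f in fractions.values())
    return ClippingReport(fractions=fractions, flagged=flagged,
                          threshold=rail_fraction_threshold)
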