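"""Back-of-envelope data volume of a time-lapse embryo incubator.

A fully loaded multi-room incubator images every embryo at a fixed
interval for days; at seven focal planes per acquisition the raw image
count motivates fusing each 7-plane stack to a single image (a 7×
reduction before any embryologist looks at the data).
"""

from __future__ import annotations

__all__ = ["incubator_image_count"]


def incubator_image_count(
    n_embryos: int = 84, hours: int = 120, interval_minutes: int = 5
) -> int:
    """Acquisitions per IVF cycle: n_embryos × hours × 60 / interval.

    Defaults describe a fully loaded 6-chamber incubator (84 embryos)
    recording for 5 days at 5-minute intervals — about 120 thousand
    acquisition events, each of which is a 7-plane focal stack.
    """
    if n_embryos <= 0 or hours <= 0 or interval_minutes <= 0:
        raise ValueError("all arguments must be positive")
    return n_embryos * hours * 60 // interval_minutes
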