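"""Model-independent moment-ratio diagnostic.

For a power-law degree distribution with alpha in (2, 3) the second moment
diverges asymptotically, so the empirical ratio <k^2>/<k>^2 should grow with
network size n.  The ratio is a model-free signal of heavy-tailed structure:
it equals 1 exactly for a regular (constant) sequence and is >= 1 always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MomentReport", "moment_ratio"]


@dataclass(frozen=True)
class MomentReport:
    n: int
    mean: float
    second_moment: float
    ratio: float


def moment_ratio(seq) -> MomentReport:
    """Exact sample moments and the ratio ``<k^2> / <k>^2``."""
    degrees = np.asarray(getattr(seq, "degrees", seq), dtype=float)
    mean = float(degrees.mean())
    if mean <= 0:
        raise ValueError("moment ratio requires positive mean degree")
    m2 = float((degrees**2).mean())
    return MomentReport(int(degrees.size), mean, m2, m2 / mean**2)
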