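"""Published model-selection tables used as worked examples.

These are the printed all-subsets selection tables from a long-term study of
reproductive investment curves in four French blue tit populations (two
deciduous-oak "fast" populations, D-Muro and D-Rouviere, and two
evergreen-oak "slow" populations, E-Muro and E-Pirio).  Each block lists the
eight candidate models over the fixed-effect pool {mean individual clutch
size, population, sex} for one response x clutch-size measure, with the
printed degrees of freedom, maximised log-likelihood, AICc, AICc difference
from the best model, and Akaike weight.

They serve as arithmetic ground truth: recomputing the weight column from
the printed deltas, the AICc column from the printed log-likelihoods, or the
retained set from the delta < 2 rule must reproduce the printed values.

Abbreviated term names: ``mic`` = mean individual clutch size, ``pop`` =
population, ``sex`` = sex.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceRow", "ReferenceBlock", "REFERENCE_BLOCKS"]


@dataclass(frozen=True)
class ReferenceRow:
    terms: tuple[str, ...]
    df: int
    loglik: float
    aicc: float
    delta: float
    weight: float


@dataclass(frozen=True)
class ReferenceBlock:
    response: str  # timescale_binary | amplitude_short | amplitude_long
    measure: str  # absolute | centred
    n_obs: int
    rows: tuple[ReferenceRow, ...]


def _rows(*specs) -> tuple[ReferenceRow, ...]:
    return tuple(ReferenceRow(tuple(t), df, ll, ai, d, w) for t, df, ll, ai, d, w in specs)


REFERENCE_BLOCKS: tuple[ReferenceBlock, ...] = (
    ReferenceBlock(
        "timescale_binary", "absolute", 787,
        _rows(
            ((), 2, -539.26, 1082.50, 0.00, 0.23),
            (("pop",), 5, -536.49, 1083.10, 0.52, 0.18),
            (("mic", "pop"), 6, -535.67, 1083.40, 0.90, 0.15),
            (("mic",), 3, -538.75, 1083.50, 0.98, 0.14),
            (("sex",), 3, -539.15, 1084.30, 1.78, 0.10),
            (("pop", "sex"), 6, -536.35, 1084.80, 2.26, 0.08),
            (("mic", "pop", "sex"), 7, -535.54, 1085.20, 2.68, 0.06),
            (("mic", "sex"), 4, -538.62, 1085.30, 2.76, 0.06),
        ),
    ),
    ReferenceBlock(
        "timescale_binary", "centred", 846,
        _rows(
            (("sex",), 3, -576.50, 1159.00, 0.00, 0.29),
            (("mic", "sex"), 4, -575.75, 1159.50, 0.51, 0.22),
            ((), 2, -578.15, 1160.30, 1.28, 0.15),
            (("pop", "sex"), 6, -574.38, 1160.90, 1.84, 0.11),
            (("mic",), 3, -577.45, 1160.90, 1.90, 0.11),
            (("pop",), 5, -576.19, 1162.40, 3.43, 0.05),
            (("mic", "pop", "sex"), 7, -574.33, 1162.80, 3.76, 0.04),
            (("mic", "pop"), 6, -576.15, 1164.40, 5.38, 0.02),
        ),
    ),
    ReferenceBlock(
        "amplitude_short", "absolute", 633,
        _rows(
            (("mic", "sex"), 5, -564.37, 1138.80, 0.00, 0.46),
            (("pop", "sex"), 7, -562.73, 1139.60, 0.80, 0.31),
            (("mic", "pop", "sex"), 8, -562.34, 1140.90, 2.07, 0.16),
            (("sex",), 4, -567.47, 1143.00, 4.17, 0.06),
            (("mic",), 4, -569.73, 1147.50, 8.69, 0.01),
            (("pop",), 6, -568.28, 1148.70, 9.87, 0.00),
            (("mic", "pop"), 7, -567.85, 1149.90, 11.05, 0.00),
            ((), 3, -572.80, 1151.60, 12.81, 0.00),
        ),
    ),
    ReferenceBlock(
        "amplitude_short", "centred", 779,
        _rows(
            (("sex",), 4, -47.32, 102.70, 0.00, 0.61),
            (("mic", "sex"), 5, -47.03, 104.10, 1.44, 0.30),
            (("pop", "sex"), 7, -46.54, 107.20, 4.54, 0.06),
            (("mic", "pop", "sex"), 8, -46.53, 109.30, 6.57, 0.02),
            ((), 3, -53.08, 112.20, 9.50, 0.01),
            (("mic",), 4, -52.75, 113.60, 10.86, 0.00),
            (("pop",), 6, -52.35, 116.80, 14.11, 0.00),
            (("mic", "pop"), 7, -52.32, 118.80, 16.10, 0.00),
        ),
    ),
    ReferenceBlock(
        "amplitude_long", "absolute", 633,
        _rows(
            (("pop", "sex"), 7, -563.69, 1141.50, 0.00, 0.54),
            (("mic", "pop", "sex"), 8, -563.62, 1143.50, 1.92, 0.21),
            (("mic", "sex"), 5, -567.01, 1144.10, 2.56, 0.15),
            (("pop",), 6, -566.86, 1145.80, 4.29, 0.06),
            (("mic", "pop"), 7, -566.77, 1147.70, 6.17, 0.02),
            (("mic",), 4, -569.87, 1147.80, 6.26, 0.02),
            (("sex",), 4, -576.16, 1160.40, 18.83, 0.00),
            ((), 3, -578.94, 1163.90, 22.38, 0.00),
        ),
    ),
    ReferenceBlock(
        "amplitude_long", "centred", 779,
        _rows(
            (("pop", "sex"), 7, 114.53, -214.90, 0.00, 0.72),
            (("mic", "pop", "sex"), 8, 114.53, -212.90, 2.04, 0.26),
            (("mic", "sex"), 5, 108.78, -207.50, 7.43, 0.02),
            (("pop",), 6, 106.90, -201.70, 13.22, 0.00),
            (("mic", "pop"), 7, 106.93, -199.70, 15.20, 0.00),
            (("sex",), 4, 103.31, -198.60, 16.35, 0.00),
            (("mic",), 4, 101.60, -195.10, 19.77, 0.00),
            ((), 3, 95.93, -185.80, 29.08, 0.00),
        ),
    ),
)
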