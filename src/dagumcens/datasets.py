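"""Bundled example data.

Quarterly UK gas consumption, 1960 Q1 through 1986 Q4 (108 values, millions
of therms) — a classic positive, right-skewed series often used to exercise
heavy-tailed lifetime models.  Stored in row order (year by year, quarters
Q1..Q4 within a year).
"""

from __future__ import annotations

import numpy as np

__all__ = ["load_gas_fixture"]

_GAS_UK_QUARTERLY = (
    # Q1, Q2, Q3, Q4 per year, 1960..1986
    (160.1, 129.7, 84.8, 120.1),
    (160.1, 124.9, 84.8, 116.9),
    (169.7, 140.9, 89.7, 132.3),
    (187.3, 144.1, 92.9, 120.1),
    (176.1, 147.3, 89.7, 123.3),
    (185.7, 155.3, 99.3, 131.3),
    (200.1, 161.7, 102.5, 136.1),
    (204.9, 176.1, 112.1, 140.9),
    (227.3, 195.3, 115.3, 142.5),
    (244.9, 214.5, 118.5, 267.3),
    (244.9, 216.1, 136.1, 336.2),
    (301.0, 196.9, 136.1, 267.3),
    (317.4, 230.5, 152.1, 336.2),
    (371.4, 240.1, 158.5, 355.4),
    (449.9, 286.6, 179.3, 403.4),
    (491.5, 321.8, 177.7, 483.5),
    (593.9, 329.8, 176.1, 483.5),
    (584.3, 395.4, 187.3, 485.1),
    (669.2, 421.0, 216.1, 509.1),
    (827.7, 467.5, 209.7, 542.7),
    (840.5, 414.6, 217.7, 670.8),
    (848.5, 437.0, 209.7, 701.2),
    (925.3, 443.4, 214.5, 683.6),
    (917.3, 515.5, 224.1, 694.8),
    (989.4, 477.1, 233.7, 730.0),
    (1087.0, 534.7, 281.8, 787.6),
    (1163.9, 613.1, 347.4, 782.8),
)


def load_gas_fixture() -> np.ndarray:
    """Return the 108 quarterly UK gas consumption values (1960 Q1–1986 Q4)."""
    return np.array([v for row in _GAS_UK_QUARTERLY for v in row], dtype=float)
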