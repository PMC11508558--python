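"""Published benchmark rankings of the 22 focus measures.

Four tables of per-criterion distances (accuracy, unimodality, width at 50%,
width at 90%, smoothness — each normalized to its per-family maximum), the
resulting Euclidean overall score and the within-family rank, as published
for the four benchmark acquisition modes:

* ``visnir_video`` — visible/NIR band, conventional video stacks,
* ``nir_video`` — NIR band, conventional video stacks,
* ``visnir_hyperspectral`` — visible/NIR band, pushbroom hyperspectral stacks,
* ``nir_hyperspectral`` — NIR band, pushbroom hyperspectral stacks.

Focus-measure labels are kept exactly as printed in the source tables
(``FTF``, ``MD-DCT`` and ``VAR`` are aliases of the registry ids ``FFT``,
``MFDCT`` and ``LOG``; see :mod:`hsfocus.measures`).

These numbers serve as regression fixtures for the scoring arithmetic in
:mod:`hsfocus.ranking`; they are inputs, never outputs, of this package.
"""

from __future__ import annotations

import pandas as pd

COLUMNS = ("fm", "d_acc", "d_uni", "d_50", "d_90", "d_smo", "overall_score", "rank")

#: fm, accuracy, unimodality, width@50%, width@90%, smoothness, overall score, rank
TABLES: dict[str, list[tuple]] = {
    "visnir_video": [
        ("TEN1", 0.10, 0.00, 0.59, 0.37, 0.59, 0.92, 1),
        ("BOD", 0.15, 0.00, 0.54, 0.46, 0.58, 0.93, 2),
        ("TEN2", 0.10, 0.00, 0.56, 0.41, 0.62, 0.94, 3),
        ("BRE", 0.05, 0.05, 0.59, 0.47, 0.60, 0.97, 4),
        ("ABG", 0.05, 0.05, 0.68, 0.60, 0.59, 1.08, 5),
        ("SAG", 0.11, 0.11, 0.59, 0.53, 0.81, 1.14, 6),
        ("EIG", 0.32, 0.12, 0.62, 0.58, 0.77, 1.20, 7),
        ("SML", 0.59, 0.33, 0.78, 0.81, 0.87, 1.57, 8),
        ("EOL", 0.20, 1.00, 0.67, 0.70, 1.00, 1.73, 9),
        ("DLF", 1.00, 0.45, 1.00, 1.00, 0.75, 1.94, 10),
        ("WL3", 0.10, 0.00, 0.55, 0.39, 0.49, 0.84, 1),
        ("WL2", 0.21, 0.19, 0.57, 0.47, 0.51, 0.94, 2),
        ("WL1", 0.18, 0.11, 0.59, 0.48, 0.53, 0.95, 3),
        ("FTF", 0.83, 0.92, 0.69, 0.76, 0.67, 1.74, 4),
        ("DCT", 1.00, 1.00, 0.74, 0.90, 0.65, 1.94, 5),
        ("MD-DCT", 0.79, 0.71, 1.00, 1.00, 1.00, 2.03, 6),
        ("NVR", 0.41, 0.45, 0.43, 0.31, 0.71, 1.08, 1),
        ("ENT", 0.31, 0.40, 0.50, 0.48, 0.75, 1.14, 2),
        ("VOL5", 0.40, 0.40, 0.61, 0.59, 0.85, 1.33, 3),
        ("ACF", 0.51, 0.55, 0.69, 0.55, 0.71, 1.36, 4),
        ("VAR", 0.46, 0.60, 0.85, 0.77, 0.78, 1.58, 5),
        ("WHS", 1.00, 1.00, 1.00, 1.00, 0.92, 2.20, 6),
    ],
    "nir_video": [
        ("TEN1", 0.30, 0.02, 0.55, 0.45, 0.50, 0.92, 1),
        ("TEN2", 0.21, 0.06, 0.61, 0.59, 0.45, 0.99, 2),
        ("ABG", 0.23, 0.02, 0.78, 0.56, 0.49, 1.10, 3),
        ("BRE", 0.58, 0.07, 0.59, 0.52, 0.59, 1.14, 4),
        ("BOD", 0.51, 0.04, 0.67, 0.61, 0.51, 1.16, 5),
        ("SAG", 0.62, 0.14, 0.69, 0.73, 0.61, 1.34, 6),
        ("EIG", 0.42, 0.32, 0.82, 0.88, 0.67, 1.47, 7),
        ("EOL", 0.73, 0.32, 0.96, 0.78, 1.00, 1.78, 8),
        ("DLF", 1.00, 0.91, 0.87, 0.93, 0.85, 2.04, 9),
        ("SML", 0.63, 1.00, 1.00, 1.00, 0.91, 2.06, 10),
        ("WL3", 0.33, 0.12, 0.50, 0.48, 0.59, 0.98, 1),
        ("WL2", 0.37, 0.22, 0.57, 0.51, 0.45, 0.99, 2),
        ("WL1", 0.41, 0.32, 0.75, 0.65, 0.59, 1.27, 3),
        ("FTF", 0.63, 0.32, 0.96, 0.87, 0.67, 1.62, 4),
        ("DCT", 0.85, 1.00, 0.87, 0.93, 0.95, 2.06, 5),
        ("MD-DCT", 1.00, 0.91, 1.00, 1.00, 1.00, 2.20, 6),
        ("VOL5", 0.40, 0.21, 0.61, 0.49, 0.65, 1.11, 1),
        ("ACF", 0.41, 0.09, 0.59, 0.65, 0.60, 1.14, 2),
        ("ENT", 0.31, 0.42, 0.56, 0.60, 0.75, 1.23, 3),
        ("NVR", 0.48, 0.13, 0.63, 0.71, 0.71, 1.29, 4),
        ("VAR", 0.76, 1.00, 0.85, 0.77, 1.00, 1.97, 5),
        ("WHS", 1.00, 0.96, 1.00, 1.00, 0.91, 2.18, 6),
    ],
    "visnir_hyperspectral": [
        ("BRE", 0.19, 0.07, 0.39, 0.35, 0.30, 0.64, 1),
        ("BOD", 0.21, 0.10, 0.37, 0.35, 0.35, 0.66, 2),
        ("EIG", 0.30, 0.12, 0.32, 0.38, 0.32, 0.67, 3),
        ("SAG", 0.29, 0.14, 0.29, 0.33, 0.41, 0.68, 4),
        ("TEN1", 0.23, 0.08, 0.45, 0.36, 0.31, 0.70, 5),
        ("TEN2", 0.21, 0.09, 0.41, 0.32, 0.42, 0.71, 6),
        ("ABG", 0.29, 0.11, 0.37, 0.40, 0.49, 0.80, 7),
        ("DLF", 0.67, 0.45, 0.87, 0.93, 0.55, 1.60, 8),
        ("EOL", 1.00, 1.00, 1.00, 0.88, 1.00, 2.19, 9),
        ("SML", 0.93, 1.00, 1.00, 1.00, 0.97, 2.19, 10),
        ("WL3", 0.23, 0.08, 0.38, 0.35, 0.31, 0.65, 1),
        ("WL2", 0.24, 0.12, 0.39, 0.41, 0.31, 0.70, 2),
        ("WL1", 0.27, 0.12, 0.41, 0.43, 0.34, 0.75, 3),
        ("FTF", 0.53, 1.00, 1.00, 0.87, 0.67, 1.87, 4),
        ("DCT", 0.75, 0.90, 0.81, 1.00, 0.95, 1.98, 5),
        ("MD-DCT", 1.00, 0.91, 0.93, 1.00, 1.00, 2.17, 6),
        ("ACF", 0.41, 0.20, 0.33, 0.34, 0.25, 0.70, 1),
        ("VOL5", 0.45, 0.31, 0.61, 0.59, 0.36, 1.07, 2),
        ("ENT", 0.41, 0.32, 0.68, 0.56, 0.45, 1.12, 3),
        ("VAR", 1.00, 0.43, 1.00, 0.67, 0.71, 1.77, 4),
        ("NVR", 0.94, 0.37, 0.91, 1.00, 0.79, 1.86, 5),
        ("WHS", 0.80, 1.00, 0.83, 0.81, 1.00, 2.00, 6),
    ],
    "nir_hyperspectral": [
        ("BOD", 0.05, 0.04, 0.37, 0.35, 0.51, 0.72, 1),
        ("TEN1", 0.15, 0.02, 0.60, 0.52, 0.50, 0.95, 2),
        ("TEN2", 0.25, 0.02, 0.64, 0.58, 0.45, 1.01, 3),
        ("ABG", 0.10, 0.02, 0.70, 0.62, 0.49, 1.06, 4),
        ("BRE", 0.19, 0.07, 0.61, 0.68, 0.59, 1.11, 5),
        ("SAG", 0.52, 0.24, 0.59, 0.60, 0.61, 1.19, 6),
        ("EIG", 0.32, 0.38, 0.42, 0.43, 1.00, 1.27, 7),
        ("SML", 1.00, 0.80, 0.50, 0.55, 0.71, 1.64, 8),
        ("DLF", 0.64, 0.71, 0.66, 0.93, 0.86, 1.72, 9),
        ("EOL", 0.73, 1.00, 1.00, 1.00, 0.85, 2.06, 10),
        ("WL3", 0.13, 0.12, 0.50, 0.47, 0.40, 0.81, 1),
        ("WL2", 0.16, 0.12, 0.59, 0.56, 0.45, 0.95, 2),
        ("WL1", 0.31, 0.32, 0.62, 0.63, 0.57, 1.14, 3),
        ("FTF", 1.00, 1.00, 0.86, 0.87, 1.00, 2.12, 4),
        ("DCT", 0.85, 0.90, 0.67, 0.73, 0.70, 1.73, 5),
        ("MD-DCT", 1.00, 0.80, 1.00, 1.00, 0.88, 2.10, 6),
        ("NVR", 0.44, 0.23, 0.59, 0.57, 0.41, 1.04, 1),
        ("ENT", 0.49, 0.12, 0.61, 0.60, 0.35, 1.05, 2),
        ("ACF", 0.57, 0.31, 0.60, 0.55, 0.68, 1.24, 3),
        ("VOL5", 0.65, 0.29, 0.71, 0.60, 0.63, 1.33, 4),
        ("VAR", 1.00, 1.00, 0.85, 0.86, 0.83, 2.04, 5),
        ("WHS", 0.91, 0.80, 1.00, 1.00, 1.00, 2.11, 6),
    ],
}


def as_dataframe(table: str) -> pd.DataFrame:
    """Return one benchmark table as a DataFrame (columns :data:`COLUMNS`)."""
    return pd.DataFrame(TABLES[table], columns=COLUMNS)


def row(table: str, fm: str) -> dict:
    """Return one table row as a dict keyed by :data:`COLUMNS`."""
    for r in TABLES[table]:
        if r[0] == fm:
            return dict(zip(COLUMNS, r))
    raise KeyError(f"{fm!r} not in table {table!r}")
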