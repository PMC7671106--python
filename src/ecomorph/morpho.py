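"""Functional jaw characters from linear cranial measurements.

Nine landmark-pair distances plus standard length and a representative tooth
height/width are converted into seven dimensionless characters describing
the feeding apparatus of a fish:

======================  =====================  =================================
character               formula                functional meaning
======================  =====================  =================================
anterior_ma             InLr / AtOL            anterior closing mechanical
                                               advantage (force vs speed)
posterior_ma            InLr / PoOL            posterior closing mechanical
                                               advantage
occlusal_offset         ArOS / PoOL            scissor-like vs precise occlusion
tooth_aspect_ratio      tooth_h / tooth_w      squat vs cuspidate teeth
symphyseal_height       MaSH / DnLn            robustness of the jaw symphysis
relative_head_length    HdLn / SL              head length vs standard length
protrusion_ratio        AsPr / PMLn            premaxillary protrusion proxy
======================  =====================  =================================

Mechanical advantage follows the standard lower-jaw lever convention,
in-lever / out-lever.  All characters are invariant to uniform scaling of a
specimen.  Denominators for the occlusal offset and symphyseal height are
configurable since no single normalisation is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementSet",
    "MorphoValidationError",
    "CHARACTERS",
    "compute_characters",
    "characters_table",
    "z_transform",
    "qq_diagnostics",
]

CHARACTERS = (
    "anterior_ma",
    "posterior_ma",
    "occlusal_offset",
    "tooth_aspect_ratio",
    "symphyseal_height",
    "relative_head_length",
    "protrusion_ratio",
)

MEASUREMENTS = (
    "SL",
    "AsPr",
    "PMLn",
    "HdLn",
    "DnLn",
    "AtOL",
    "PoOL",
    "ArOS",
    "InLr",
    "MaSH",
    "tooth_height",
    "tooth_width",
)


class MorphoValidationError(ValueError):
    """Raised for non-positive lengths or degenerate columns."""


@dataclass(frozen=True)
class MeasurementSet:
    """Linear measurements (mm) for one specimen."""

    species: str
    SL: float
    AsPr: float
    PMLn: float
    HdLn: float
    DnLn: float
    AtOL: float
    PoOL: float
    ArOS: float
    InLr: float
    MaSH: float
    tooth_height: float
    tooth_width: float
    specimen_id: str = ""

    def __post_init__(self) -> None:
        for name in MEASUREMENTS:
            v = getattr(self, name)
            if name == "ArOS":
                if v < 0:
                    raise MorphoValidationError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise MorphoValidationError(f"{name} must be > 0, got {v}")


def compute_characters(
    m: MeasurementSet,
    occlusal_denominator: str = "PoOL",
    symphysis_denominator: str = "DnLn",
) -> dict[str, float]:
    """The seven functional jaw characters for one specimen."""
    for arg, allowed in (
        (occlusal_denominator, ("PoOL", "DnLn")),
        (symphysis_denominator, ("DnLn", "PoOL")),
    ):
        if arg not in allowed:
            raise MorphoValidationError(f"denominator {arg!r} not in {allowed}")
    return {
        "anterior_ma": m.InLr / m.AtOL,
        "posterior_ma": m.InLr / m.PoOL,
        "occlusal_offset": m.ArOS / getattr(m, occlusal_denominator),
        "tooth_aspect_ratio": m.tooth_height / m.tooth_width,
        "symphyseal_height": m.MaSH / getattr(m, symphysis_denominator),
        "relative_head_length": m.HdLn / m.SL,
        "protrusion_ratio": m.AsPr / m.PMLn,
    }


def characters_table(
    specimens: list[MeasurementSet], **kwargs
) -> pd.DataFrame:
    """Species x 7-character table (species averaged over their specimens)."""
    rows = []
    for m in specimens:
        row = {"species": m.species}
        row.update(compute_characters(m, **kwargs))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.groupby("species", sort=True).mean()


def z_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization, (x - mean) / sd with the n-1 denominator."""
    if len(table) < 2:
        raise MorphoValidationError("need at least 2 species to standardize")
    sd = table.std(axis=0, ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise MorphoValidationError(f"zero-variance columns: {dead}")
    return (table - table.mean(axis=0)) / sd


def qq_diagnostics(table: pd.DataFrame) -> dict[str, dict]:
    """Normal quantile-quantile pairs for each character, for plotting.

    Returns, per column, the (theoretical, sample) quantile pairs and a
    ``degenerate`` flag for constant columns.  No decision rule is applied;
    normality is a visual judgement.
    """
    out = {}
    for col in table.columns:
        x = np.sort(np.asarray(table[col], dtype=float))
        n = len(x)
        if n < 3:
            raise MorphoValidationError("need at least 3 values per column")
        if np.allclose(x, x[0]):
            out[col] = {"theoretical": [], "sample": [], "degenerate": True}
            continue
        probs = (np.arange(1, n + 1) - 0.5) / n
        out[col] = {
            "theoretical": stats.norm.ppf(probs).tolist(),
            "sample": x.tolist(),
            "degenerate": False,
        }
    return out
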