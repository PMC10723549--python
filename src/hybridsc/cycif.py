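"""cyCIF quantification: threshold gating, percent-positive, Welch's t.

Input is a per-cell mean-fluorescent-intensity table (one column per
marker).  Gating classifies each cell as

* ``hybrid`` — CD45 at/above threshold together with at least one
  melanocyte marker (MITF, TYR, MLANA, GP100, HTR2B) at/above threshold,
  EXCEPT cells whose only melanocyte positivity is HTR2B and which are
  also CD25- or CD203c-positive: those are ``excluded`` because they
  cannot be distinguished from basophil or regulatory-T populations;
* ``tumor`` — at least one melanocyte marker positive with CD45, CD25 and
  CD203c all below threshold;
* ``other`` — everything else.

Positivity is inclusive (``intensity >= threshold``).  Percent positive is
``100 x positive / total`` within a class, and group comparisons use
Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import welch_t

__all__ = [
    "GateConfig",
    "gate_cells",
    "percent_positive",
    "compare_groups",
    "thresholds_from_negative_controls",
]

DEFAULT_MELANOCYTE = ("MITF", "TYR", "MLANA", "GP100", "HTR2B")
DEFAULT_PHENOTYPE = ("TMSB10", "CD74", "GPX1")


@dataclass
class GateConfig:
    """Marker roles and per-marker minimum intensity thresholds."""

    melanocyte_markers: tuple[str, ...] = DEFAULT_MELANOCYTE
    leukocyte_marker: str = "CD45"
    exclusion_markers: tuple[str, ...] = ("CD25", "CD203c")
    phenotype_markers: tuple[str, ...] = DEFAULT_PHENOTYPE
    thresholds: dict[str, float] = field(default_factory=dict)
    default_threshold: float = 200.0
    # strict reading: cells positive for a non-HTR2B melanocyte marker stay
    # eligible even when CD25/CD203c positive; set False to exclude any
    # CD25/CD203c-positive candidate.
    htr2b_only_exclusion: bool = True

    def threshold(self, marker: str) -> float:
        value = self.thresholds.get(marker, self.default_threshold)
        if value <= 0:
            raise ValueError(f"threshold for {marker!r} must be positive")
        return value

    def all_markers(self) -> list[str]:
        return [
            *self.melanocyte_markers,
            self.leukocyte_marker,
            *self.exclusion_markers,
            *self.phenotype_markers,
        ]


def thresholds_from_negative_controls(
    controls: pd.DataFrame, markers, quantile: float = 0.99
) -> dict[str, float]:
    """Per-marker thresholds as a high quantile of negative-control intensity."""
    return {m: float(controls[m].quantile(quantile)) for m in markers}


def gate_cells(intensities: pd.DataFrame, config: GateConfig | None = None) -> pd.DataFrame:
    """Classify cells and flag phenotype-marker positivity.

    Returns a frame with ``cell_id``, ``cell_class`` in
    {hybrid, tumor, excluded, other} and one boolean ``<marker>_positive``
    column per phenotype marker.
    """
    config = config or GateConfig()
    missing = [m for m in config.all_markers() if m not in intensities.columns]
    if missing:
        raise ValueError(f"missing marker columns: {missing}")

    pos = {m: intensities[m].to_numpy() >= config.threshold(m) for m in config.all_markers()}
    mel = np.column_stack([pos[m] for m in config.melanocyte_markers])
    any_mel = mel.any(axis=1)
    cd45 = pos[config.leukocyte_marker]
    excl_pos = np.column_stack([pos[m] for m in config.exclusion_markers]).any(axis=1)

    non_htr2b = [m for m in config.melanocyte_markers if m != "HTR2B"]
    only_htr2b = (
        pos.get("HTR2B", np.zeros(len(intensities), bool))
        & ~np.column_stack([pos[m] for m in non_htr2b]).any(axis=1)
        if non_htr2b
        else pos.get("HTR2B", np.zeros(len(intensities), bool))
    )

    hybrid_candidate = cd45 & any_mel
    if config.htr2b_only_exclusion:
        excluded = hybrid_candidate & only_htr2b & excl_pos
    else:
        excluded = hybrid_candidate & excl_pos
    hybrid = hybrid_candidate & ~excluded
    tumor = any_mel & ~cd45 & ~excl_pos

    cell_class = np.full(len(intensities), "other", dtype=object)
    cell_class[tumor] = "tumor"
    cell_class[hybrid] = "hybrid"
    cell_class[excluded] = "excluded"

    out = pd.DataFrame(
        {"cell_id": intensities["cell_id"].to_numpy(), "cell_class": cell_class}
    )
    for m in config.phenotype_markers:
        out[f"{m}_positive"] = pos[m]
    return out


def percent_positive(gates: pd.DataFrame, cell_class: str, marker: str) -> float:
    """``100 x positive / total`` among cells of ``cell_class``.

    Raises when no cell of the class exists — the percentage is undefined,
    not zero.
    """
    sub = gates[gates["cell_class"] == cell_class]
    if len(sub) == 0:
        raise ValueError(f"no cells of class {cell_class!r}; percentage undefined")
    col = f"{marker}_positive"
    if col not in gates.columns:
        raise ValueError(f"marker {marker!r} was not gated")
    return 100.0 * float(sub[col].sum()) / float(len(sub))


def compare_groups(values_a, values_b) -> tuple[float, float, float]:
    """Welch's t-test between two groups of per-sample percentages."""
    return welch_t(values_a, values_b)
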