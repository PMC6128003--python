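"""Chlorophyll content from absorbance readings and electrolyte leakage.

Chlorophyll (mg per g fresh weight) from 80% acetone extract absorbances
at 663 nm and 645 nm, extract volume V (ml) and fresh weight W (mg):

    chl_a     = (12.7 * A663 - 2.69 * A645) * V / W / 1000
    chl_b     = (22.9 * A645 - 4.86 * A663) * V / W / 1000
    chl_total = (8.02 * A663 - 20.20 * A645) * V / W / 1000   (as printed)

The printed total disagrees in sign with chl_a + chl_b (whose A645
coefficient is +20.21); ``mode="arnon_corrected"`` flips the total's
minus to the internally consistent plus (the classic Arnon form
8.02*A663 + 20.20*A645). The as-printed form stays the default so the
source protocol is reproduced verbatim.

Electrolyte leakage is EL1/EL2 * 100, with EL1 the conductivity of the
bathing solution after incubation and EL2 the total conductivity after
boiling the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .expression import ttest_annotate
from .types import RlkfamError


def chlorophyll(
    a663: float, a645: float, v_ml: float, w_mg: float, mode: str = "as_printed"
) -> tuple[float, float, float]:
    """(chl_a, chl_b, chl_total) in mg/g fresh weight."""
    if v_ml <= 0 or w_mg <= 0:
        raise RlkfamError("extract volume and fresh weight must be positive")
    if a663 < 0 or a645 < 0:
        raise RlkfamError("absorbances must be non-negative")
    scale = v_ml / w_mg / 1000.0
    chl_a = (12.7 * a663 - 2.69 * a645) * scale
    chl_b = (22.9 * a645 - 4.86 * a663) * scale
    if mode == "as_printed":
        total = (8.02 * a663 - 20.20 * a645) * scale
    elif mode == "arnon_corrected":
        total = (8.02 * a663 + 20.20 * a645) * scale
    else:
        raise RlkfamError(f"unknown chlorophyll mode {mode!r}")
    return chl_a, chl_b, total


def electrolyte_leakage(el1: float, el2: float) -> float:
    """Percent leakage 100 * EL1 / EL2."""
    if el2 <= 0:
        raise RlkfamError("EL2 (total conductivity) must be positive")
    if el1 < 0 or el1 > el2:
        raise RlkfamError("EL1 must satisfy 0 <= EL1 <= EL2")
    return 100.0 * el1 / el2


PHYSIO_COLUMNS = ["sample_id", "group", "a663", "a645", "v_ml", "w_mg", "el1", "el2"]


def read_physiology(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PHYSIO_COLUMNS) - set(df.columns)
    if missing:
        raise RlkfamError(f"{path}: missing physiology columns {sorted(missing)}")
    return df


@dataclass
class GroupComparison:
    metric: str
    mean_control: float
    mean_treated: float
    sd_control: float
    sd_treated: float
    t: float
    p: float
    stars: str


def compare_groups(
    df: pd.DataFrame,
    control: str = "control",
    treated: str = "silenced",
    chlorophyll_mode: str = "as_printed",
    welch: bool = False,
) -> list[GroupComparison]:
    """Per-metric control-vs-treated comparison with star annotation.

    Metrics: total chlorophyll (mg/g) and electrolyte leakage (%), plus
    any optional growth columns present (shoot/root length, fresh/dry
    weight).
    """
    values: dict[str, dict[str, list[float]]] = {}

    def push(metric: str, group: str, value: float) -> None:
        values.setdefault(metric, {}).setdefault(group, []).append(value)

    for row in df.itertuples(index=False):
        _, _, total = chlorophyll(
            row.a663, row.a645, row.v_ml, row.w_mg, mode=chlorophyll_mode
        )
        push("chlorophyll_total_mg_g", row.group, total)
        push("electrolyte_leakage_pct", row.group, electrolyte_leakage(row.el1, row.el2))
    for extra in ("shoot_cm", "root_cm", "fresh_g", "dry_g"):
        if extra in df.columns:
            for row in df.itertuples(index=False):
                push(extra, row.group, float(getattr(row, extra)))

    out: list[GroupComparison] = []
    for metric, groups in values.items():
        if control not in groups or treated not in groups:
            raise RlkfamError(f"{metric}: missing group {control!r} or {treated!r}")
        a, b = pd.Series(groups[control]), pd.Series(groups[treated])
        t, p, stars = ttest_annotate(a, b, welch=welch)
        out.append(
            GroupComparison(
                metric=metric,
                mean_control=float(a.mean()),
                mean_treated=float(b.mean()),
                sd_control=float(a.std(ddof=1)),
                sd_treated=float(b.std(ddof=1)),
                t=t,
                p=p,
                stars=stars,
            )
        )
    return out


def comparison_table(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])
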