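"""Packaged reference tables: registration QC and per-tumour growth records.

Two measurement tables from the in vivo study this simulator models are
shipped as CSV fixtures for validation:

* the registration QC table — per-mouse lung-mask volumes at weeks 13 and 18
  plus the Dice coefficient of the registered masks, for 6 control and 12
  urethane mice;
* the growth table — per-tumour volumes (mm^3) for the 9 trackable urethane
  mice at weeks 13 and 18, with printed TTV/AVT/SDV summary rows. A "-" early
  entry marks a tumour first visible at week 18.

Fixture integrity is guarded by SHA-256 checksums frozen at packaging time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from crbssfp.errors import CorruptFixtureError

_CHECKSUMS = {
    "table1.csv": "49874a48edaa870c642d40d241beb1ce15d34fb8746b196ad33079c2ebc3974b",
    "table2.csv": "bd81b186a968559b8c61ed96b22e14c9189e9a71e1c21f146e015044d76d34cf",
    "table2_summary.csv": "4c9aea09eff8351b4480e240515a50a29916831df4e0a718b0a0b2823bf4d415",
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("crbssfp.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise CorruptFixtureError(f"{name}: checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


@dataclass(frozen=True)
class TableFixtures:
    """Typed access to the packaged reference tables."""

    qc: pd.DataFrame        # mouse, group, mask volumes w13/w18, dice
    tumours: pd.DataFrame   # mouse, tumour, volume_w13_mm3 (float or NaN), volume_w18_mm3
    summaries: pd.DataFrame  # mouse, week, TTV, AVT, SDV (as printed)

    def qc_record(self, mouse: str) -> tuple:
        row = self.qc.set_index("mouse").loc[mouse]
        return (
            float(row.mask_volume_w13_mm3),
            float(row.mask_volume_w18_mm3),
            float(row.dice),
        )

    def mask_volumes(self, group: str, week: str = "w18") -> np.ndarray:
        col = f"mask_volume_{week}_mm3"
        return self.qc.loc[self.qc.group == group, col].to_numpy(float)

    def urethane_dice(self) -> np.ndarray:
        return self.qc.loc[self.qc.group == "urethane", "dice"].to_numpy(float)

    def tumour_volumes(self, mouse: str) -> pd.DataFrame:
        return self.tumours[self.tumours.mouse == mouse].reset_index(drop=True)

    def min_tumour_volume(self) -> float:
        both = pd.concat(
            [self.tumours.volume_w13_mm3.dropna(), self.tumours.volume_w18_mm3]
        )
        return float(both.min())


def load_table_fixtures() -> TableFixtures:
    """Load and validate the packaged reference tables.

    Raises
    ------
    CorruptFixtureError
        On checksum mismatch or unexpected row/column structure.
    """
    qc = _read_fixture("table1.csv")
    tumours = _read_fixture("table2.csv")
    tumours["volume_w13_mm3"] = pd.to_numeric(
        tumours["volume_w13_mm3"].replace("-", np.nan)
    )
    tumours["volume_w18_mm3"] = pd.to_numeric(tumours["volume_w18_mm3"])
    summaries = _read_fixture("table2_summary.csv")

    if len(qc) != 18 or set(qc.group) != {"control", "urethane"}:
        raise CorruptFixtureError("QC table must contain 18 mice in two groups")
    if (qc.group == "urethane").sum() != 12 or (qc.group == "control").sum() != 6:
        raise CorruptFixtureError("QC table group sizes must be 12 + 6")
    mice = sorted(set(tumours.mouse))
    if len(mice) != 9:
        raise CorruptFixtureError("growth table must cover 9 mice")
    per_mouse = tumours.groupby("mouse").size()
    if per_mouse.max() > 18:
        raise CorruptFixtureError("growth table has more than 18 tumours for a mouse")
    if len(summaries) != 18:  # 9 mice x 2 timepoints
        raise CorruptFixtureError("summary table must have 9 x 2 rows")
    return TableFixtures(qc=qc, tumours=tumours, summaries=summaries)
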