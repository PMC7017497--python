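"""Sample metadata: identity and context of each gut sample.

Every downstream stage keys on :class:`SampleRecord`: which mouse a sample
came from, its treatment group (functional tail cup ``TC-F``, mock tail cup
``TC-M``, wire floor ``WF``, standard housing ``CTRL``), the gastrointestinal
site (stomach ``STM``; proximal/middle/distal small intestine ``SI1``/``SI2``/
``SI3``; cecum ``CEC``; colon ``COL``; gallbladder bile ``BILE``), the material
(lumenal contents, mucosal scraping, or bile), and the bookkeeping needed to
express assay readouts per normalization unit (sample mass or DNA input, and
the dilution chain from sample to reaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd

GROUPS = ("TC-F", "TC-M", "WF", "CTRL")
SITES = ("STM", "SI1", "SI2", "SI3", "CEC", "COL", "BILE")
MATERIALS = ("contents", "mucosa", "bile")

#: groups whose mice retain access to feces (practice coprophagy)
COPROPHAGIC_GROUPS = ("TC-M", "WF", "CTRL")
#: sites upstream of the cecum
UPPER_GIT_SITES = ("STM", "SI1", "SI2", "SI3")
SMALL_INTESTINE_SITES = ("SI1", "SI2", "SI3")


@dataclass
class SampleRecord:
    """One gut sample and the unit bookkeeping attached to it.

    ``dilution_factor`` is the net scalar taking a concentration measured in
    the assay reaction (or reconstituted extract) back to the sample
    normalization unit; it encodes the whole extraction/dilution chain.
    """

    sample_id: str
    mouse_id: str
    group: str
    site: str
    material: str = "contents"
    mass_g: Optional[float] = None
    dna_input_ng: Optional[float] = None
    dilution_factor: float = 1.0
    dna_conc_ng_ul: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if self.site not in SITES:
            raise ValueError(
                f"sample {self.sample_id}: unknown site {self.site!r}; "
                f"expected one of {SITES}"
            )
        if self.material not in MATERIALS:
            raise ValueError(
                f"sample {self.sample_id}: unknown material {self.material!r}"
            )
        if self.dilution_factor <= 0:
            raise ValueError(f"sample {self.sample_id}: dilution_factor must be > 0")

    @property
    def is_coprophagic(self) -> bool:
        return self.group in COPROPHAGIC_GROUPS


_META_COLUMNS = [
    "sample_id",
    "mouse_id",
    "group",
    "site",
    "material",
    "mass_g",
    "dna_input_ng",
    "dilution_factor",
    "dna_conc_ng_ul",
]


def metadata_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d.pop("extra")
        rows.append(d)
    df = pd.DataFrame(rows, columns=_META_COLUMNS)
    return df


def frame_to_metadata(df: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _META_COLUMNS:
            v = row.get(col)
            if pd.isna(v):
                v = None
            kwargs[col] = v
        if kwargs["dilution_factor"] is None:
            kwargs["dilution_factor"] = 1.0
        records.append(SampleRecord(**kwargs))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s) in metadata: {dupes}")
    keys = [(r.mouse_id, r.site, r.material) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("(mouse, site, material) combinations are not unique")
    return records


def write_metadata(records: list[SampleRecord], path) -> None:
    metadata_to_frame(records).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleRecord]:
    return frame_to_metadata(pd.read_csv(path, sep="\t"))
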