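"""Domain types and TSV readers/writers for long-format count tables.

A dataset is two tab-separated files: a counts table with columns
``taxon_id``, ``sample_id``, ``count`` and a metadata table with columns
``sample_id``, ``grain``, ``inoculant``, ``period_days``, ``replicate``.
Factor levels are closed sets matching the ensiling factorial: grains
corn/sorghum, inoculants CTRL/Inoc1/Inoc2 (CTRL is the untreated control,
Inoc1/Inoc2 the two bacterial additives), and fermentation periods
0, 3, 7, 21, 90 and 360 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

GRAIN_LEVELS = ("corn", "sorghum")
INOCULANT_LEVELS = ("CTRL", "Inoc1", "Inoc2")
PERIOD_LEVELS = (0, 3, 7, 21, 90, 360)

COUNT_COLUMNS = ["taxon_id", "sample_id", "count"]
META_COLUMNS = ["sample_id", "grain", "inoculant", "period_days", "replicate"]


@dataclass(frozen=True)
class SampleMeta:
    """Factorial coordinates of one sequenced sample."""

    sample_id: str
    grain: str
    inoculant: str
    period_days: int
    replicate: int

    def __post_init__(self) -> None:
        if self.grain not in GRAIN_LEVELS:
            raise ValidationError(
                f"unknown grain {self.grain!r}; allowed levels: {GRAIN_LEVELS}"
            )
        if self.inoculant not in INOCULANT_LEVELS:
            raise ValidationError(
                f"unknown inoculant {self.inoculant!r}; allowed levels: {INOCULANT_LEVELS}"
            )
        if self.period_days not in PERIOD_LEVELS:
            raise ValidationError(
                f"unknown period {self.period_days!r}; allowed levels: {PERIOD_LEVELS}"
            )
        if not (isinstance(self.replicate, int) and self.replicate >= 1):
            raise ValidationError(f"replicate must be a positive integer, got {self.replicate!r}")


@dataclass
class CountTable:
    """Long-format taxon x sample read counts plus per-sample metadata.

    ``records`` is a list of ``(taxon_id, sample_id, count)`` tuples with at
    most one record per (taxon, sample) pair; ``metadata`` maps every
    sample_id appearing in the records (and possibly more) to its
    :class:`SampleMeta`.
    """

    records: list[tuple[str, str, int]]
    metadata: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for taxon, sample, count in self.records:
            if sample not in self.metadata:
                raise ValidationError(f"sample {sample!r} in counts has no metadata row")
            if not isinstance(count, (int,)) or isinstance(count, bool):
                raise ValidationError(f"count for ({taxon!r}, {sample!r}) is not an integer")
            if count < 0:
                raise ValidationError(f"negative count {count} for ({taxon!r}, {sample!r})")
            key = (taxon, sample)
            if key in seen:
                raise ValidationError(f"duplicate record for ({taxon!r}, {sample!r})")
            seen.add(key)

    @property
    def taxa(self) -> list[str]:
        return sorted({t for t, _, _ in self.records})

    @property
    def samples(self) -> list[str]:
        return sorted({s for _, s, _ in self.records})

    def densify(self, fill_zeros: bool = True) -> "CountTable":
        """Return a table with an explicit record for every (taxon, sample) pair.

        OTU tables imply zeros for absent pairs; ``fill_zeros=False`` returns
        the table unchanged for workflows that treat absence as missing.
        """
        if not fill_zeros:
            return self
        present = {(t, s): c for t, s, c in self.records}
        records = [
            (t, s, present.get((t, s), 0))
            for t in self.taxa
            for s in self.samples
        ]
        return CountTable(records=records, metadata=dict(self.metadata))

    def subset(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = set(sample_ids)
        return CountTable(
            records=[r for r in self.records if r[1] in keep],
            metadata={s: m for s, m in self.metadata.items() if s in keep},
        )

    def split_by_grain(self) -> dict[str, "CountTable"]:
        """One table per grain, mirroring the per-grain model fits."""
        out: dict[str, CountTable] = {}
        for grain in GRAIN_LEVELS:
            ids = [s for s, m in self.metadata.items() if m.grain == grain]
            if any(r[1] in set(ids) for r in self.records):
                out[grain] = self.subset(ids)
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        counts = pd.DataFrame(self.records, columns=COUNT_COLUMNS)
        meta = pd.DataFrame(
            [
                (m.sample_id, m.grain, m.inoculant, m.period_days, m.replicate)
                for m in self.metadata.values()
            ],
            columns=META_COLUMNS,
        ).sort_values("sample_id", ignore_index=True)
        return counts, meta


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_count_table(counts_path: str | Path, metadata_path: str | Path) -> CountTable:
    """Read counts and metadata TSVs into a validated :class:`CountTable`.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` for bad counts, unknown factor levels or samples
    lacking metadata.
    """
    counts_path, metadata_path = Path(counts_path), Path(metadata_path)
    counts = pd.read_csv(counts_path, sep="\t", dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    _check_columns(counts, COUNT_COLUMNS, counts_path)
    _check_columns(meta, META_COLUMNS, metadata_path)

    metadata: dict[str, SampleMeta] = {}
    for row in meta.itertuples(index=False):
        try:
            period = int(row.period_days)
            replicate = int(row.replicate)
        except ValueError as exc:
            raise ValidationError(f"{metadata_path}: non-integer period/replicate: {exc}") from exc
        sm = SampleMeta(
            sample_id=row.sample_id,
            grain=row.grain,
            inoculant=row.inoculant,
            period_days=period,
            replicate=replicate,
        )
        if sm.sample_id in metadata:
            raise ValidationError(f"{metadata_path}: duplicate sample_id {sm.sample_id!r}")
        metadata[sm.sample_id] = sm
    cells = [(m.grain, m.inoculant, m.period_days, m.replicate) for m in metadata.values()]
    if len(set(cells)) != len(cells):
        raise ValidationError(f"{metadata_path}: (grain, inoculant, period, replicate) not unique")

    records: list[tuple[str, str, int]] = []
    for row in counts.itertuples(index=False):
        try:
            c = int(row.count)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{counts_path}: count {row.count!r} for ({row.taxon_id!r}, {row.sample_id!r}) "
                "is not an integer"
            ) from None
        records.append((row.taxon_id, row.sample_id, c))
    return CountTable(records=records, metadata=metadata)


def write_count_table(table: CountTable, counts_path: str | Path, metadata_path: str | Path) -> None:
    """Write the table back to the two-TSV on-disk format."""
    counts, meta = table.to_frames()
    counts.to_csv(counts_path, sep="\t", index=False)
    meta.to_csv(metadata_path, sep="\t", index=False)


def metadata_frame(metadata: Mapping[str, SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.sample_id, m.grain, m.inoculant, m.period_days, m.replicate)
            for m in metadata.values()
        ],
        columns=META_COLUMNS,
    )
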