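"""TSV readers and writers for the pipeline's tabular interfaces.

Formats:

* water samples: id, source, temperature_c, ph, sc_ms_cm, d13c_dic_permil
  (temperature_c and sc_ms_cm may be empty);
* carbonate samples: id, core, depth_top_cm, depth_bottom_cm,
  d13c_caco3_permil;
* count table: first column feature id, remaining columns samples, header
  row required; metadata: sample_id, group.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ecology import CountTable
from .geochem import BiosignatureResult, CarbonateSample, WaterSample

WATER_COLUMNS = ["id", "source", "temperature_c", "ph", "sc_ms_cm", "d13c_dic_permil"]
CARBONATE_COLUMNS = ["id", "core", "depth_top_cm", "depth_bottom_cm", "d13c_caco3_permil"]


def _opt(value) -> float | None:
    return None if value is None or (isinstance(value, float) and math.isnan(value)) else float(value)


def read_water_samples(path: str | Path) -> list[WaterSample]:
    df = pd.read_csv(path, sep="\t")
    missing = set(WATER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing water-sample columns {sorted(missing)}")
    return [
        WaterSample(
            id=str(row.id),
            source=str(row.source),
            temperature=_opt(row.temperature_c),
            ph=float(row.ph),
            conductance=_opt(row.sc_ms_cm),
            delta13c_dic=float(row.d13c_dic_permil),
        )
        for row in df.itertuples()
    ]


def write_water_samples(samples: Sequence[WaterSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id,
                "source": s.source,
                "temperature_c": s.temperature,
                "ph": s.ph,
                "sc_ms_cm": s.conductance,
                "d13c_dic_permil": s.delta13c_dic,
            }
            for s in samples
        ],
        columns=WATER_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_carbonate_samples(path: str | Path) -> list[CarbonateSample]:
    df = pd.read_csv(path, sep="\t")
    missing = set(CARBONATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing carbonate-sample columns {sorted(missing)}")
    return [
        CarbonateSample(
            id=str(row.id),
            core=str(row.core),
            depth_top=float(row.depth_top_cm),
            depth_bottom=float(row.depth_bottom_cm),
            delta13c_caco3=float(row.d13c_caco3_permil),
        )
        for row in df.itertuples()
    ]


def write_carbonate_samples(samples: Sequence[CarbonateSample], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": s.id,
                "core": s.core,
                "depth_top_cm": s.depth_top,
                "depth_bottom_cm": s.depth_bottom,
                "d13c_caco3_permil": s.delta13c_caco3,
            }
            for s in samples
        ],
        columns=CARBONATE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_count_table(counts_path: str | Path, metadata_path: str | Path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ValueError(f"{metadata_path}: metadata needs 'sample_id' and 'group' columns")
    groups = dict(zip(meta["sample_id"].astype(str), meta["group"].astype(str)))
    counts.columns = counts.columns.astype(str)
    return CountTable(counts=counts, groups=groups)


def write_count_table(table: CountTable, counts_path: str | Path, metadata_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample_id": list(table.groups), "group": list(table.groups.values())}
    ).to_csv(metadata_path, sep="\t", index=False)


def write_biosignature_report(result: BiosignatureResult, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": result.sample_ids,
            "offset_permil": result.offsets,
            "classification": result.classifications,
        }
    ).to_csv(path, sep="\t", index=False)


def write_summary(values: dict, path: str | Path) -> None:
    """Machine-readable key<TAB>value summary file."""
    with open(path, "w") as fh:
        for k, v in values.items():
            fh.write(f"{k}\t{v}\n")
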