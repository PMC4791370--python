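"""Delimited-text readers and writers for the pipeline's tables.

All on-disk formats are TSV: peak lists (long format with a sample_id
column, or one file per sample), the DOM table (samples x formula strings),
the OTU table with a separate taxonomy map, and the environmental table.
"""

from __future__ import annotations

import pathlib
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .community_prep import OtuTable
from .formula_pipeline import MassPeak

PEAK_COLUMNS = ("mz", "intensity", "resolution", "sn")


def write_peak_lists(
    peak_lists: Mapping[str, Iterable[MassPeak]], path: str | pathlib.Path
) -> None:
    """Write all samples' peaks as one long-format TSV."""
    rows = [
        {
            "sample_id": s, "mz": pk.mz, "intensity": pk.intensity,
            "resolution": pk.resolution, "sn": pk.sn,
        }
        for s, pks in peak_lists.items()
        for pk in pks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peak_lists(path: str | pathlib.Path) -> dict[str, list[MassPeak]]:
    """Read peak lists from a long-format TSV or a directory of TSVs."""
    path = pathlib.Path(path)
    frames: list[pd.DataFrame] = []
    if path.is_dir():
        for f in sorted(path.glob("*.tsv")):
            df = pd.read_csv(f, sep="\t")
            if "sample_id" not in df.columns:
                df["sample_id"] = f.stem
            frames.append(df)
    else:
        frames.append(pd.read_csv(path, sep="\t"))
    out: dict[str, list[MassPeak]] = {}
    for df in frames:
        missing = set(PEAK_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"peak list missing columns: {sorted(missing)}")
        for row in df.itertuples(index=False):
            out.setdefault(str(row.sample_id), []).append(
                MassPeak(
                    mz=float(row.mz), intensity=float(row.intensity),
                    resolution=float(row.resolution), sn=float(row.sn),
                    sample_id=str(row.sample_id),
                )
            )
    return out


def write_table(df: pd.DataFrame, path: str | pathlib.Path) -> None:
    df.to_csv(path, sep="\t")


def read_table(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_otu_table(t: OtuTable, counts_path, taxonomy_path) -> None:
    t.counts.to_csv(counts_path, sep="\t")
    t.taxonomy.rename("taxonomy").to_csv(taxonomy_path, sep="\t")


def read_otu_table(counts_path, taxonomy_path=None) -> OtuTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)["taxonomy"]
    return OtuTable(counts=counts, taxonomy=taxonomy)


def read_contaminant_masses(path: str | pathlib.Path) -> list[float]:
    """One neutral mass (Da) per line; blank lines and # comments ignored."""
    out = []
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(float(line))
    return out


def write_manifest(manifest: dict, path: str | pathlib.Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | pathlib.Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
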