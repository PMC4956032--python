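"""Trait data: the packaged 56-species theropod table and a validated reader.

The packaged table records, per species, femur length in cm (a body-size
proxy for bipedal non-avian theropods) and whether rugose metaplastic
projections are present (1) or absent (0) on the dorsal neural spines.
Rows whose femur length was estimated rather than measured in the original
description carry the ``femur_estimated`` flag.

The morphological coding rules that produced the binary character require
specimen examination and are shipped here only as a documented vocabulary
(``CODING_RATIONALE``), not as automated calls.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "TraitTableError",
    "load_table1",
    "load_standin_tree",
    "read_trait_table",
    "ln_femur",
    "CODING_RATIONALE",
]

#: Vocabulary for the "coding rationale" column of user tables: why a taxon
#: was assigned 0 or 1.  Applying these rules is a specimen-level judgment.
CODING_RATIONALE = {
    "full_height_metaplasia": 1,   # projections span spine height and apex
    "margin_exceeding_metaplasia": 1,  # projections extend past spine margins
    "caudal_only_projections": 0,  # projections confined to caudal vertebrae
    "apex_flaring": 0,             # rounded lateral flaring of the spine apex
    "periosteal_hooks": 0,         # hook-like periosteal (not metaplastic) structures
    "scarring_not_projecting": 0,  # visible ligament scars that do not project
    "absent": 0,
}

_TABLE1_SHA256 = "35a00365590b11ad9eb1f115cb50431b7d336830e5a7decd8488f1dfda40b4c1"


class TraitTableError(ValueError):
    """Invalid trait-table content."""


@dataclass
class TraitTable:
    """Validated taxon / femur-length / binary-character table."""

    df: pd.DataFrame  # columns: taxon, femur_cm, projections, femur_estimated

    def __post_init__(self) -> None:
        df = self.df
        problems = []
        dup = df["taxon"][df["taxon"].duplicated()].tolist()
        if dup:
            problems.append(f"duplicate taxa: {sorted(set(dup))}")
        bad_femur = df.loc[~(df["femur_cm"] > 0), "taxon"].tolist()
        if bad_femur:
            problems.append(f"non-positive femur length for: {bad_femur}")
        bad_code = df.loc[~df["projections"].isin([0, 1]), "taxon"].tolist()
        if bad_code:
            problems.append(
                f"projection codes must be 0 (absent) or 1 (present); bad rows: {bad_code}"
            )
        if problems:
            raise TraitTableError("; ".join(problems))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list[str]:
        return self.df["taxon"].tolist()

    @property
    def femur_cm(self) -> np.ndarray:
        return self.df["femur_cm"].to_numpy(float)

    @property
    def projections(self) -> np.ndarray:
        return self.df["projections"].to_numpy(int)

    def ln_femur(self) -> np.ndarray:
        return np.log(self.femur_cm)

    def row(self, taxon: str) -> pd.Series:
        hit = self.df[self.df["taxon"] == taxon]
        if hit.empty:
            raise KeyError(taxon)
        return hit.iloc[0]

    def subset(self, taxa: list[str]) -> "TraitTable":
        """Rows for ``taxa``, in the given order."""
        idx = self.df.set_index("taxon")
        missing = [t for t in taxa if t not in idx.index]
        if missing:
            raise TraitTableError(f"taxa absent from table: {missing}")
        return TraitTable(idx.loc[taxa].reset_index())


def ln_femur(table: TraitTable) -> np.ndarray:
    """Natural log of femur length (ln cm), in table order."""
    return table.ln_femur()


def _packaged(name: str) -> str:
    return resources.files("spinetrait.data").joinpath(name).read_text()


def load_table1() -> TraitTable:
    """The packaged 56-species table, verbatim at printed precision.

    A checksum guards against accidental modification of the packaged file.
    """
    text = _packaged("table1.tsv")
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise TraitTableError(
            f"packaged trait table is corrupted (sha256 {digest[:12]}...)"
        )
    df = pd.read_csv(
        _io_str(text), sep="\t",
        dtype={"taxon": str, "femur_cm": float, "projections": int, "femur_estimated": int},
    )
    df["femur_estimated"] = df["femur_estimated"].astype(bool)
    return TraitTable(df)


def load_standin_tree():
    """The packaged 56-taxon tree.

    SYNTHETIC STAND-IN: the original analysis used a tree extracted from a
    published dinosaur supertree whose topology and branch lengths are not
    reproduced in the source; this packaged tree is a synthetic substitute
    with literature-informed clade groupings and Grafen-style (clade-size)
    branch lengths scaled to unit depth.  Use your own calibrated tree for
    any substantive reanalysis.
    """
    from .treeio import read_tree

    return read_tree(_packaged("standin_tree_synthetic.nwk"), "newick")


def _io_str(text: str):
    import io

    return io.StringIO(text)


def read_trait_table(
    path,
    delimiter: str | None = None,
    column_map: dict | None = None,
) -> TraitTable:
    """Read and validate a delimited trait table.

    ``column_map`` maps the package's canonical column names (taxon,
    femur_cm, projections, femur_estimated) to the file's header names.
    Delimiter defaults to tab for .tsv and comma otherwise.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith(".tsv") else ","
    raw = pd.read_csv(path, sep=delimiter)
    cmap = {"taxon": "taxon", "femur_cm": "femur_cm", "projections": "projections"}
    if column_map:
        cmap.update(column_map)
    missing = [v for v in (cmap["taxon"], cmap["femur_cm"], cmap["projections"]) if v not in raw.columns]
    if missing:
        raise TraitTableError(f"missing columns in {path}: {missing}")
    df = pd.DataFrame(
        {
            "taxon": raw[cmap["taxon"]].astype(str).str.strip(),
            "femur_cm": pd.to_numeric(raw[cmap["femur_cm"]], errors="coerce"),
            "projections": pd.to_numeric(raw[cmap["projections"]], errors="coerce"),
        }
    )
    est_col = cmap.get("femur_estimated", "femur_estimated")
    df["femur_estimated"] = (
        raw[est_col].astype(int).astype(bool) if est_col in raw.columns else False
    )
    bad_num = df.loc[df["femur_cm"].isna() | df["projections"].isna(), "taxon"].tolist()
    if bad_num:
        raise TraitTableError(f"non-numeric femur/projection values for rows: {bad_num}")
    nonint = df.loc[df["projections"] != df["projections"].astype(int), "taxon"].tolist()
    if nonint:
        raise TraitTableError(
            f"projection codes must be integer 0/1; bad rows: {nonint}"
        )
    df["projections"] = df["projections"].astype(int)
    return TraitTable(df)
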