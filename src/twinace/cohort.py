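"""Twin-cohort container and delimited-text I/O.

A cohort is a long-format table of individuals nested in families: each row is
one twin, identified by ``(family_id, twin_order)``, with zygosity shared
within the family.  Families with a single row are legal ("unpaired
responders") and contribute marginal information to full-information
likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: fixed leading columns of the cohort CSV schema
ID_COLUMNS = ["family_id", "zygosity", "twin_order", "sex", "age"]

PHENO_PREFIX = "pheno_"
ITEM_PREFIX = "item_"


class CohortError(ValueError):
    """Structural problem with a twin cohort."""


@dataclass
class TwinCohort:
    """Long-format twin data.

    Parameters
    ----------
    data
        One row per individual.  Must contain ``family_id`` (any hashable id),
        ``zygosity`` ("MZ"/"DZ"), ``twin_order`` (1 or 2), ``sex`` (0/1) and
        ``age`` (years), plus ``pheno_<name>`` and/or ``item_<scale>_<k>``
        columns.  Missing values are NaN.
    meta
        Free-form provenance (generating spec, seed, ...); written to the
        sidecar config on save.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort is missing required columns: {missing}")
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if not df["zygosity"].isin(["MZ", "DZ"]).all():
            raise CohortError("zygosity must be 'MZ' or 'DZ'")
        if not df["twin_order"].isin([1, 2]).all():
            raise CohortError("twin_order must be 1 or 2")
        sizes = df.groupby("family_id").size()
        if (sizes > 2).any():
            bad = sizes[sizes > 2].index.tolist()[:5]
            raise CohortError(f"families with more than two records: {bad}")
        if df.duplicated(subset=["family_id", "twin_order"]).any():
            raise CohortError("duplicate (family_id, twin_order) records")
        nzyg = df.groupby("family_id")["zygosity"].nunique()
        if (nzyg > 1).any():
            raise CohortError("co-twins with discordant zygosity labels")

    @property
    def phenotype_names(self) -> list[str]:
        return [c[len(PHENO_PREFIX):] for c in self.data.columns
                if c.startswith(PHENO_PREFIX)]

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(ITEM_PREFIX)]

    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def complete_pairs(self, zygosity: str | None = None) -> pd.DataFrame:
        """Families with both twins present, one row per family.

        Returns a frame indexed by family_id with ``_1``/``_2`` suffixed
        phenotype columns (twin order 1 and 2).
        """
        df = self.data
        if zygosity is not None:
            df = df[df["zygosity"] == zygosity]
        sizes = df.groupby("family_id")["twin_order"].transform("size")
        paired = df[sizes == 2]
        wide = paired.pivot(index="family_id", columns="twin_order")
        wide.columns = [f"{c}_{o}" for c, o in wide.columns]
        return wide

    def singles(self) -> pd.DataFrame:
        sizes = self.data.groupby("family_id")["twin_order"].transform("size")
        return self.data[sizes == 1]

    # -- numeric views for the likelihood engine ---------------------------
    def to_arrays(self, traits: Sequence[str]) -> dict:
        """Stacked observation arrays per group, NaN marking missingness.

        Pairs give rows ``[twin1 traits..., twin2 traits...]`` (2p wide);
        singles give p-wide rows.  Used by the FIML engine.
        """
        cols = [PHENO_PREFIX + t for t in traits]
        unknown = [c for c in cols if c not in self.data.columns]
        if unknown:
            raise CohortError(f"unknown phenotype columns: {unknown}")
        out: dict = {}
        for zyg in ("MZ", "DZ"):
            wide = self.complete_pairs(zygosity=zyg)
            if len(wide):
                arr = np.column_stack(
                    [wide[f"{c}_1"].to_numpy(float) for c in cols]
                    + [wide[f"{c}_2"].to_numpy(float) for c in cols])
            else:
                arr = np.empty((0, 2 * len(cols)))
            out[zyg] = arr
        singles = self.singles()
        out["single"] = (singles[cols].to_numpy(float)
                         if len(singles) else np.empty((0, len(cols))))
        return out

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path, sidecar: bool = True) -> None:
        """Write the cohort CSV (UTF-8, header row, empty field = missing)."""
        self.data.to_csv(path, index=False, na_rep="")
        if sidecar and self.meta:
            with open(str(path) + ".meta.yaml", "w") as fh:
                yaml.safe_dump(_plain(self.meta), fh, sort_keys=True)

    @classmethod
    def read_csv(cls, path) -> "TwinCohort":
        df = pd.read_csv(path)
        df["twin_order"] = df["twin_order"].astype(int)
        meta: dict = {}
        try:
            with open(str(path) + ".meta.yaml") as fh:
                meta = yaml.safe_load(fh) or {}
        except FileNotFoundError:
            pass
        return cls(df, meta=meta)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
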