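"""Bundled 31-species trait table and its transforms.

Each record holds the mean cylinder-task success (%), the altricial-period
length (age at fledging for birds, age at weaning for mammals, days) and
lifespan (days).  Derived columns: natural logs of the two durations and the
angular (arcsine-square-root) transform of the success proportion.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "TREE_NAME_ALIASES",
    "arcsine_pct",
    "ln_transform",
    "load_table",
    "bundled_table_path",
    "bundled_tree_path",
    "add_derived_columns",
    "tree_label",
]

REQUIRED_COLUMNS = ["species", "cylinder_pct", "fw_days", "lifespan_days"]

#: Table spellings that differ from the chronogram tip labels.  The bundled
#: table preserves the published spellings (including the misspelt pigeon and
#: snub-nosed monkey binomials); matching to tree tips goes through this
#: explicit map rather than fuzzy matching.
TREE_NAME_ALIASES = {
    "Columbia livia": "Columba_livia",
    "Rhinopithecuas roxellana": "Rhinopithecus_roxellana",
    "Aphelocoma califórnica": "Aphelocoma_californica",
}


class TableValidationError(ValueError):
    pass


def bundled_table_path():
    return resources.files("altripgls.data") / "table1.csv"


def bundled_tree_path(n_species: int = 31):
    if n_species not in (31, 32):
        raise ValueError("bundled chronograms have 31 or 32 species")
    return resources.files("altripgls.data") / f"chronogram_{n_species}sp.nwk"


def tree_label(species: str) -> str:
    """Chronogram tip label for a table species name."""
    return TREE_NAME_ALIASES.get(species, species.replace(" ", "_"))


def arcsine_pct(p, mode: str = "sqrt"):
    """Arcsine transform of a percentage, in radians.

    ``sqrt`` (default) is the angular transform asin(sqrt(p/100)), the
    standard variance stabilizer for proportions; ``plain`` is asin(p/100).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentage outside [0, 100]")
    if mode == "sqrt":
        out = np.arcsin(np.sqrt(arr / 100.0))
    elif mode == "plain":
        out = np.arcsin(arr / 100.0)
    else:
        raise ValueError(f"unknown arcsine mode {mode!r}")
    return float(out) if np.isscalar(p) else out


def ln_transform(x):
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ln requires strictly positive values")
    out = np.log(arr)
    return float(out) if np.isscalar(x) else out


def add_derived_columns(df: pd.DataFrame, arcsine_mode: str = "sqrt") -> pd.DataFrame:
    """Attach ln_fw, ln_life and asin_cyl columns (idempotent)."""
    out = df.copy()
    out["ln_fw"] = ln_transform(out["fw_days"].to_numpy())
    out["ln_life"] = ln_transform(out["lifespan_days"].to_numpy())
    out["asin_cyl"] = arcsine_pct(out["cylinder_pct"].to_numpy(), arcsine_mode)
    return out


def load_table(path=None, arcsine_mode: str = "sqrt") -> pd.DataFrame:
    """Load and validate a species trait table, adding derived columns."""
    if path is None:
        path = bundled_table_path()
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing columns: {missing}")
    for col in ("cylinder_pct", "fw_days", "lifespan_days"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals.isna(), "species"].tolist()
        if bad:
            raise TableValidationError(f"non-numeric {col} for rows {bad}")
        df[col] = vals.astype(float)
    dupes = df.loc[df["species"].duplicated(), "species"].tolist()
    if dupes:
        raise TableValidationError(f"duplicate species: {dupes}")
    if (df["fw_days"] >= df["lifespan_days"]).any():
        bad = df.loc[df["fw_days"] >= df["lifespan_days"], "species"].tolist()
        raise TableValidationError(f"rearing period >= lifespan for {bad}")
    if ((df["cylinder_pct"] < 0) | (df["cylinder_pct"] > 100)).any():
        raise TableValidationError("cylinder_pct outside [0, 100]")
    return add_derived_columns(df, arcsine_mode)
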