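"""CSV and flat key-value serialization for campaign artefacts.

Schemas
-------
Plot table CSV: ``plot_id`` column, one column per covariate axis, and one
``sp_<name>`` 0/1 column per species. Score table CSV: ``species, axis,
expert, category`` with the closed category vocabulary (case-insensitive
on read, canonical lower-case on write). Species truth and campaign
configuration use a flat ``key = value`` format: one pair per line, ``#``
comments, list values comma-separated, nested names dotted
(``mode1.optima = 800, 10, ...``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .elicitation import validate_scores
from .synthetic import CovariateSpace, NicheMode, VirtualSpecies

__all__ = [
    "read_keyvalues", "write_keyvalues",
    "load_species", "save_species",
    "load_plots", "save_plots",
    "load_scores", "save_scores",
]

CSV_FLOAT_FORMAT = "%.10g"  # fixed format keeps rerun outputs byte-identical


def read_keyvalues(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        key = key.strip()
        if key in out:
            raise ValueError(f"{path}: line {lineno}: duplicate key {key!r}")
        out[key] = value.strip()
    return out


def write_keyvalues(pairs: dict[str, str], path) -> None:
    lines = [f"{k} = {v}" for k, v in pairs.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _floats(value: str) -> tuple[float, ...]:
    return tuple(float(v) for v in value.split(","))


def save_species(species: VirtualSpecies, path) -> None:
    pairs: dict[str, str] = {
        "name": species.name,
        "max_probability": f"{species.max_probability:.12g}",
        "n_modes": str(len(species.components)),
    }
    for i, mode in enumerate(species.components, start=1):
        pairs[f"mode{i}.optima"] = ", ".join(f"{v:.12g}" for v in mode.optima)
        pairs[f"mode{i}.breadths"] = ", ".join(f"{v:.12g}" for v in mode.breadths)
        pairs[f"mode{i}.weight"] = f"{mode.weight:.12g}"
    write_keyvalues(pairs, path)


def load_species(path) -> VirtualSpecies:
    kv = read_keyvalues(path)
    n = int(kv["n_modes"])
    modes = tuple(
        NicheMode(
            optima=_floats(kv[f"mode{i}.optima"]),
            breadths=_floats(kv[f"mode{i}.breadths"]),
            weight=float(kv[f"mode{i}.weight"]),
        )
        for i in range(1, n + 1)
    )
    return VirtualSpecies(name=kv["name"], components=modes,
                          max_probability=float(kv["max_probability"]))


def save_plots(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def load_plots(path, space: CovariateSpace | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["plot_id"])
    if df.empty and "plot_id" not in df.columns:
        return df
    if "plot_id" not in df.columns:
        raise ValueError(f"{path}: plot table lacks a plot_id column")
    if space is not None:
        missing = [c for c in space.names if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing covariate columns {missing}")
        na = df[list(space.names)].isna()
        if na.any().any():
            rows = [int(i) + 2 for i in df.index[na.any(axis=1)][:10]]  # 1-based + header
            raise ValueError(f"{path}: missing covariate values at rows {rows}")
    for col in [c for c in df.columns if c.startswith("sp_")]:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad][:10]]
            raise ValueError(f"{path}: non-binary presence in {col!r} at rows {rows}")
    return df


def save_scores(scores: pd.DataFrame, path) -> None:
    validate_scores(scores).to_csv(path, index=False)


def load_scores(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["species", "axis", "expert", "category"])
    if df.empty:
        return pd.DataFrame(columns=["species", "axis", "expert", "category"])
    try:
        return validate_scores(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
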