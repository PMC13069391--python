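"""Reading, validating and summarising OTU-labelled morphometric tables.

The expected table layout follows the usual convention for linear
morphometrics: one row per specimen, column 1 the OTU (putative taxon)
label, column 2 a body-size character (e.g. snout--vent length), and the
remaining columns further continuous characters.  All measurements must be
strictly positive because downstream allometric correction works on
log10-transformed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorphoDataset",
    "SchemeFile",
    "MorphoWarning",
    "ValidationError",
    "read_morphometrics",
    "write_morphometrics",
    "summarize",
    "flag_outliers",
    "read_schemes",
]

#: consistency constant making the MAD estimate sigma for Gaussian data
MAD_SCALE = 1.4826


class MorphoWarning(UserWarning):
    """Non-fatal data-quality issue (singleton OTU, skipped group, ...)."""


class ValidationError(ValueError):
    """The input table violates a structural requirement."""


@dataclass
class MorphoDataset:
    """A specimen-by-character matrix with OTU labels and a body-size column.

    Parameters
    ----------
    specimen_ids
        Unique identifier per specimen (row order defines alignment with
        scheme files).
    otu_labels
        OTU (group) label per specimen.
    body_size
        The designated body-size measurement per specimen (same units as
        measured, e.g. mm).
    characters
        ``(n, d)`` array of the remaining continuous characters.
    character_names
        ``d`` unique column names.
    body_size_name
        Name of the body-size column.
    log_scale
        ``True`` once values have been log10-transformed (set by the
        allometry layer); guards against double correction.
    """

    specimen_ids: list[str]
    otu_labels: np.ndarray
    body_size: np.ndarray
    characters: np.ndarray
    character_names: list[str]
    body_size_name: str = "SVL"
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.otu_labels = np.asarray(self.otu_labels, dtype=object)
        self.body_size = np.asarray(self.body_size, dtype=float)
        self.characters = np.atleast_2d(np.asarray(self.characters, dtype=float))
        self.specimen_ids = [str(s) for s in self.specimen_ids]
        n = len(self.specimen_ids)
        if n < 2:
            raise ValidationError("at least 2 specimens are required")
        if len(set(self.specimen_ids)) != n:
            dupes = sorted({s for s in self.specimen_ids if self.specimen_ids.count(s) > 1})
            raise ValidationError(f"duplicate specimen ids: {dupes}")
        if self.characters.shape[0] != n or self.otu_labels.shape[0] != n or self.body_size.shape[0] != n:
            raise ValidationError("specimen_ids, otu_labels, body_size and characters disagree in length")
        if self.characters.shape[1] != len(self.character_names):
            raise ValidationError("character_names does not match the number of character columns")
        if len(set(self.character_names)) != len(self.character_names):
            raise ValidationError("character names must be unique")
        values = np.column_stack([self.body_size, self.characters])
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"missing or non-finite value for specimen {self.specimen_ids[i]!r}, "
                f"column {( [self.body_size_name] + list(self.character_names) )[j]!r}"
            )
        if not self.log_scale and np.any(values <= 0):
            i, j = np.argwhere(values <= 0)[0]
            raise ValidationError(
                f"non-positive value for specimen {self.specimen_ids[i]!r}, column "
                f"{([self.body_size_name] + list(self.character_names))[j]!r}: "
                "all measurements must be > 0 (log10 transform is applied downstream)"
            )
        for otu in self.singletons():
            warnings.warn(f"OTU {otu!r} has a single specimen (singleton)", MorphoWarning, stacklevel=2)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_characters(self) -> int:
        return self.characters.shape[1]

    @property
    def otus(self) -> list[str]:
        return sorted(set(self.otu_labels))

    def otu_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.otu_labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def singletons(self) -> list[str]:
        return [otu for otu, c in self.otu_counts().items() if c == 1]

    def drop_singletons(self) -> "MorphoDataset":
        """Return a copy without singleton OTUs (warning-free)."""
        keep = ~np.isin(self.otu_labels.astype(str), self.singletons())
        return MorphoDataset(
            [s for s, k in zip(self.specimen_ids, keep) if k],
            self.otu_labels[keep],
            self.body_size[keep],
            self.characters[keep],
            list(self.character_names),
            self.body_size_name,
            self.log_scale,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.characters, columns=list(self.character_names))
        df.insert(0, self.body_size_name, self.body_size)
        df.insert(0, "OTU", self.otu_labels.astype(str))
        df.index = pd.Index(self.specimen_ids, name="specimen")
        return df

    def matrix(self, include_body_size: bool = False) -> np.ndarray:
        if include_body_size:
            return np.column_stack([self.body_size, self.characters])
        return self.characters.copy()


@dataclass
class SchemeFile:
    """Named taxonomic hypotheses: a group label per specimen per scheme.

    Labels are free strings, so a scheme may lump OTUs under one label or
    split a single OTU into several groups.
    """

    specimen_ids: list[str]
    schemes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, labels in self.schemes.items():
            labels = np.asarray(labels, dtype=object)
            if labels.shape[0] != len(self.specimen_ids):
                raise ValidationError(f"scheme {name!r} length does not match specimen ids")
            if any(str(v).strip() == "" or pd.isna(v) for v in labels):
                raise ValidationError(f"scheme {name!r} contains empty group labels")
            self.schemes[name] = labels

    def groups(self, name: str) -> list[str]:
        return sorted(set(self.schemes[name].astype(str)))


def read_morphometrics(path, *, sep: str = ",") -> MorphoDataset:
    """Read a morphometric CSV (col 1 = OTU, col 2 = body size, cols 3+ = characters).

    Specimen ids are taken from the 1-based row number.  Non-numeric cells,
    missing values and non-positive measurements raise :class:`ValidationError`
    naming the offending cell; singleton OTUs trigger a :class:`MorphoWarning`.
    """
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 3:
        raise ValidationError("expected at least 3 columns: OTU, body size, >=1 character")
    otu_col = df.columns[0]
    numeric_cols = list(df.columns[1:])
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"non-numeric value {df[col].iloc[row]!r} in row {row + 1}, column {col!r}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValidationError(f"missing value in row {row + 1}, column {col!r}")
        df[col] = coerced
    if df[otu_col].isna().any():
        row = int(np.flatnonzero(df[otu_col].isna().to_numpy())[0])
        raise ValidationError(f"missing OTU label in row {row + 1}")
    ids = [str(i + 1) for i in range(len(df))]
    return MorphoDataset(
        specimen_ids=ids,
        otu_labels=df[otu_col].astype(str).to_numpy(dtype=object),
        body_size=df[numeric_cols[0]].to_numpy(float),
        characters=df[numeric_cols[1:]].to_numpy(float),
        character_names=[str(c) for c in numeric_cols[1:]],
        body_size_name=str(numeric_cols[0]),
    )


def write_morphometrics(ds: MorphoDataset, path, *, header_comments: dict | None = None) -> None:
    """Write a dataset back to CSV in the canonical column layout."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header_comments or {}).items():
            fh.write(f"# {key}: {value}\n")
        ds.to_frame().to_csv(fh, index=False, lineterminator="\n")


def summarize(ds: MorphoDataset) -> pd.DataFrame:
    """Per (OTU, character) descriptive statistics: N, mean, SD, min, max.

    The body-size column is included as a character.  SD uses the n-1
    denominator and is reported as NaN for single-specimen OTUs.
    """
    df = ds.to_frame()
    long = df.melt(id_vars=["OTU"], var_name="character", value_name="value")
    out = (
        long.groupby(["OTU", "character"], sort=True)["value"]
        .agg(N="count", mean="mean", sd=lambda v: v.std(ddof=1), min="min", max="max")
        .reset_index()
    )
    order = [ds.body_size_name] + list(ds.character_names)
    out["character"] = pd.Categorical(out["character"], categories=order, ordered=True)
    return out.sort_values(["OTU", "character"]).reset_index(drop=True)


def format_summary(table: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Publication-style strings ``N; mean ± SD; min—max`` per (OTU, character)."""
    def fmt(row):
        sd = "NA" if pd.isna(row["sd"]) else f"{row['sd']:.{digits}f}"
        return (f"{int(row['N'])}; {row['mean']:.{digits}f} ± {sd}; "
                f"{row['min']:.{digits}f}—{row['max']:.{digits}f}")
    wide = table.assign(cell=table.apply(fmt, axis=1)).pivot(index="OTU", columns="character", values="cell")
    return wide


def flag_outliers(ds: MorphoDataset, threshold: float = 3.5) -> pd.DataFrame:
    """Robust within-OTU outlier screen.

    For every OTU and character the score is ``|x - median| / (MAD * 1.4826)``;
    rows with score above ``threshold`` are returned sorted by descending
    score.  OTUs with fewer than 3 specimens, and zero-spread groups
    (MAD = 0), are skipped with a warning.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    ids = np.asarray(ds.specimen_ids, dtype=object)
    names = [ds.body_size_name] + list(ds.character_names)
    values = np.column_stack([ds.body_size, ds.characters])
    rows = []
    for otu in ds.otus:
        mask = ds.otu_labels.astype(str) == otu
        if mask.sum() < 3:
            warnings.warn(f"OTU {otu!r} has < 3 specimens; outlier screen skipped", MorphoWarning, stacklevel=2)
            continue
        sub = values[mask]
        med = np.median(sub, axis=0)
        mad = np.median(np.abs(sub - med), axis=0)
        for j, name in enumerate(names):
            if mad[j] == 0:
                if np.all(sub[:, j] == med[j]):
                    warnings.warn(
                        f"OTU {otu!r}, character {name!r}: zero spread (MAD = 0); skipped",
                        MorphoWarning, stacklevel=2,
                    )
                    continue
                # a majority of identical values: anything off the median is
                # infinitely many MADs away
                score = np.where(sub[:, j] == med[j], 0.0, np.inf)
            else:
                score = np.abs(sub[:, j] - med[j]) / (mad[j] * MAD_SCALE)
            hit = score > threshold
            for sid, val, sc in zip(ids[mask][hit], sub[hit, j], score[hit]):
                rows.append({"specimen": sid, "OTU": otu, "character": name, "value": val, "score": sc})
    out = pd.DataFrame(rows, columns=["specimen", "OTU", "character", "value", "score"])
    return out.sort_values("score", ascending=False).reset_index(drop=True)


def read_schemes(path, ds: MorphoDataset, *, sep: str = ",") -> SchemeFile:
    """Read a scheme CSV (col 1 = specimen id, cols 2+ = named schemes) aligned to ``ds``.

    The id sets must match exactly; rows are re-ordered to the dataset's
    specimen order.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("scheme file needs an id column plus >=1 scheme column")
    id_col = df.columns[0]
    file_ids = df[id_col].astype(str).tolist()
    missing = sorted(set(ds.specimen_ids) - set(file_ids))
    extra = sorted(set(file_ids) - set(ds.specimen_ids))
    if missing or extra:
        raise ValidationError(
            f"scheme file ids do not match the dataset (missing: {missing or 'none'}; extra: {extra or 'none'})"
        )
    df = df.set_index(id_col).loc[ds.specimen_ids]
    schemes = {str(c): df[c].to_numpy(dtype=object) for c in df.columns}
    return SchemeFile(specimen_ids=list(ds.specimen_ids), schemes=schemes)
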