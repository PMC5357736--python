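"""Spectrum matrix container and delimited-text IO.

A :class:`SpectrumMatrix` holds a samples x spectral-variables intensity
matrix on an explicit ascending chemical-shift (ppm) axis, together with
per-sample annotations (subject, diet, day, collection window).  Every stage
of the pipeline consumes and returns this container.

On disk a spectrum matrix is a TSV whose header is ``sample_id`` followed by
the ppm values as decimal text, one row per sample.  Annotations are a
separate TSV keyed by ``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumMatrix",
    "read_spectra",
    "write_spectra",
    "read_annotations",
    "write_annotations",
]

#: Columns every annotation table carries (extra columns are preserved).
ANNOTATION_COLUMNS = ("subject_id", "diet", "day", "collection")


@dataclass
class SpectrumMatrix:
    """Samples x spectral-variables intensity matrix with ppm axis.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``intensities``.
    ppm : ndarray
        Strictly ascending chemical-shift axis, length = number of columns.
    intensities : ndarray
        2-D array of shape ``(n_samples, n_points)``.
    annotations : DataFrame, optional
        Indexed by sample_id; typically carries subject_id, diet, day,
        collection and (for synthetic cohorts) the planted dilution_factor.
    """

    sample_ids: list[str]
    ppm: np.ndarray
    intensities: np.ndarray
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        n, p = self.intensities.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} intensity rows"
            )
        if len(set(self.sample_ids)) != n:
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.ppm.shape != (p,):
            raise ValueError("ppm axis length must match number of columns")
        if p >= 2 and not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm axis must be strictly ascending")
        if self.annotations is not None:
            missing = set(self.sample_ids) - set(self.annotations.index.astype(str))
            if missing:
                raise ValueError(f"annotations missing sample ids: {sorted(missing)}")

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def row(self, sample_id: str) -> np.ndarray:
        return self.intensities[self.sample_ids.index(sample_id)]

    def annotation_frame(self) -> pd.DataFrame:
        """Annotations reindexed to row order (raises if absent)."""
        if self.annotations is None:
            raise ValueError("spectrum matrix carries no annotations")
        return self.annotations.loc[self.sample_ids]

    # -- derived matrices ----------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "SpectrumMatrix":
        """Row subset in the given order; annotations follow."""
        idx = []
        for s in sample_ids:
            if s not in self.sample_ids:
                raise KeyError(f"unknown sample id: {s}")
            idx.append(self.sample_ids.index(s))
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[list(sample_ids)]
        return SpectrumMatrix(
            list(sample_ids), self.ppm.copy(), self.intensities[idx].copy(), ann
        )

    def select_where(self, **conditions) -> "SpectrumMatrix":
        """Subset samples whose annotation matches, e.g. ``diet=1, day=3``.

        A condition value may be a scalar or a collection of admissible
        values.
        """
        ann = self.annotation_frame()
        mask = np.ones(self.n_samples, dtype=bool)
        for key, val in conditions.items():
            col = ann[key].to_numpy()
            if isinstance(val, (list, tuple, set, frozenset, np.ndarray)):
                mask &= np.isin(col, list(val))
            else:
                mask &= col == val
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return self.subset_samples(ids)

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumMatrix":
        return SpectrumMatrix(
            list(self.sample_ids), self.ppm.copy(), intensities, self.annotations
        )

    def copy(self) -> "SpectrumMatrix":
        ann = None if self.annotations is None else self.annotations.copy()
        return SpectrumMatrix(
            list(self.sample_ids), self.ppm.copy(), self.intensities.copy(), ann
        )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def write_spectra(matrix: SpectrumMatrix, path) -> None:
    """Write a spectrum matrix as TSV: header ``sample_id`` then ppm values."""
    df = pd.DataFrame(
        matrix.intensities,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=[repr(float(v)) for v in matrix.ppm],
    )
    df.to_csv(path, sep="\t")


def read_spectra(path, annotations: pd.DataFrame | None = None) -> SpectrumMatrix:
    """Read a spectrum matrix TSV written by :func:`write_spectra`.

    Raises ``ValueError`` on duplicate sample ids, non-numeric cells (with
    the offending line number) or a non-ascending ppm header.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    ids = df["sample_id"].tolist()
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate sample ids: {dupes}")
    try:
        ppm = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric ppm header: {exc}") from exc
    if len(ppm) >= 2 and not np.all(np.diff(ppm) > 0):
        raise ValueError(f"{path}: ppm header must be strictly ascending")
    values = np.empty((len(ids), len(ppm)))
    body = df.iloc[:, 1:].to_numpy()
    for i in range(len(ids)):
        try:
            values[i] = body[i].astype(float)
        except ValueError as exc:
            raise ValueError(
                f"{path}: non-numeric intensity on line {i + 2}: {exc}"
            ) from exc
    return SpectrumMatrix(ids, ppm, values, annotations)


def write_annotations(annotations: pd.DataFrame, path) -> None:
    annotations.rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return df
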