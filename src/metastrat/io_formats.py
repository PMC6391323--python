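"""Readers, writers and core domain types for peak tables and libraries.

Peak tables are plain CSV/TSV files with features as rows: a ``mz`` column,
an ``rt`` column, then one intensity column per sample.  Missing intensities
are empty cells or ``NA``.  Sample metadata lives in a companion CSV with
columns ``sample_id,group,experiment``.  Reference libraries are TSV files
with columns ``metabolite_id,name,neutral_mass``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_CASE = "case"
GROUP_CONTROL = "control"
VALID_GROUPS = (GROUP_CASE, GROUP_CONTROL)


@dataclasses.dataclass
class PeakTable:
    """Feature x sample intensity matrix with m/z, RT and sample metadata.

    Parameters
    ----------
    mz, rt :
        Per-feature mass-to-charge (Da) and retention time (seconds).
    intensities :
        ``(n_features, n_samples)`` float array; ``NaN`` encodes missing.
    sample_ids, groups, experiments :
        Per-sample identifier, class label (``case``/``control``) and
        experiment (batch) tag.
    """

    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    groups: np.ndarray
    experiments: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = np.asarray(self.groups, dtype=object)
        self.experiments = np.asarray(self.experiments, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        nf, ns = self.intensities.shape
        if self.mz.shape != (nf,) or self.rt.shape != (nf,):
            raise ValueError(
                f"feature key length {self.mz.shape[0]} does not match "
                f"intensity rows {nf}"
            )
        if len(self.sample_ids) != ns or self.groups.shape != (ns,) or \
                self.experiments.shape != (ns,):
            raise ValueError(
                f"sample annotation length does not match intensity "
                f"columns ({ns})"
            )
        if np.any(self.mz <= 0):
            bad = int(np.argmax(self.mz <= 0))
            raise ValueError(f"non-positive m/z at feature row {bad}")
        seen: set[str] = set()
        for s in self.sample_ids:
            if s in seen:
                raise ValueError(f"duplicate sample ID {s!r}")
            seen.add(s)
        for s, g in zip(self.sample_ids, self.groups):
            if g not in VALID_GROUPS:
                raise ValueError(
                    f"unknown group label {g!r} for sample {s!r} "
                    f"(expected one of {VALID_GROUPS})"
                )
        if GROUP_CASE not in self.groups or GROUP_CONTROL not in self.groups:
            raise ValueError("table must contain at least one case and one control")
        observed = self.intensities[~np.isnan(self.intensities)]
        if observed.size and np.any(observed < 0):
            raise ValueError("negative intensity encountered")

    # -- convenience ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_features, n_samples)`` mask, True where missing."""
        return np.isnan(self.intensities)

    @property
    def feature_keys(self) -> list[tuple[float, float]]:
        return [(float(m), float(r)) for m, r in zip(self.mz, self.rt)]

    @property
    def case_mask(self) -> np.ndarray:
        return self.groups == GROUP_CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.groups == GROUP_CONTROL

    def copy(self) -> "PeakTable":
        return PeakTable(
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            intensities=self.intensities.copy(),
            sample_ids=list(self.sample_ids),
            groups=self.groups.copy(),
            experiments=self.experiments.copy(),
        )

    def subset_samples(self, idx: np.ndarray) -> "PeakTable":
        idx = np.asarray(idx)
        return PeakTable(
            mz=self.mz.copy(),
            rt=self.rt.copy(),
            intensities=self.intensities[:, idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            groups=self.groups[idx].copy(),
            experiments=self.experiments[idx].copy(),
        )

    def subset_features(self, idx: np.ndarray) -> "PeakTable":
        idx = np.asarray(idx)
        return PeakTable(
            mz=self.mz[idx].copy(),
            rt=self.rt[idx].copy(),
            intensities=self.intensities[idx, :].copy(),
            sample_ids=list(self.sample_ids),
            groups=self.groups.copy(),
            experiments=self.experiments.copy(),
        )


def concat_samples(a: PeakTable, b: PeakTable) -> PeakTable:
    """Column-concatenate two tables that share identical feature keys.

    Colliding sample IDs are suffixed with their experiment tag (a warning
    is logged) so the result remains a valid table.
    """
    if a.n_features != b.n_features or not (
        np.array_equal(a.mz, b.mz) and np.array_equal(a.rt, b.rt)
    ):
        raise ValueError("cannot concatenate tables with differing feature keys")
    ids_a = list(a.sample_ids)
    ids_b = list(b.sample_ids)
    collisions = set(ids_a) & set(ids_b)
    if collisions:
        logger.warning(
            "sample-ID collision between experiments (%d ids); suffixing "
            "with experiment tag", len(collisions)
        )
        ids_a = [
            f"{s}__{e}" if s in collisions else s
            for s, e in zip(ids_a, a.experiments)
        ]
        ids_b = [
            f"{s}__{e}" if s in collisions else s
            for s, e in zip(ids_b, b.experiments)
        ]
        still = set(ids_a) & set(ids_b)  # same experiment tag on both sides
        if still:
            ids_a = [f"{s}__a" if s in still else s for s in ids_a]
            ids_b = [f"{s}__b" if s in still else s for s in ids_b]
    return PeakTable(
        mz=a.mz.copy(),
        rt=a.rt.copy(),
        intensities=np.hstack([a.intensities, b.intensities]),
        sample_ids=ids_a + ids_b,
        groups=np.concatenate([a.groups, b.groups]),
        experiments=np.concatenate([a.experiments, b.experiments]),
    )


@dataclasses.dataclass
class ReferenceLibrary:
    """Metabolite records against which detected peaks are annotated."""

    metabolite_ids: list[str]
    names: list[str]
    neutral_masses: np.ndarray

    def __post_init__(self) -> None:
        self.neutral_masses = np.asarray(self.neutral_masses, dtype=float)
        n = len(self.metabolite_ids)
        if len(self.names) != n or self.neutral_masses.shape != (n,):
            raise ValueError("library field lengths differ")
        if len(set(self.metabolite_ids)) != n:
            raise ValueError("duplicate metabolite_id in library")
        if np.any(self.neutral_masses <= 0):
            raise ValueError("non-positive neutral mass in library")

    def __len__(self) -> int:
        return len(self.metabolite_ids)


@dataclasses.dataclass(frozen=True)
class TrueMarkerSet:
    """Gold-standard metabolite identifiers used for enrichment scoring."""

    metabolite_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.metabolite_ids:
            raise ValueError("true-marker set is empty")

    def __len__(self) -> int:
        return len(self.metabolite_ids)

    def __contains__(self, item: str) -> bool:
        return item in self.metabolite_ids


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_peak_table(path: str | Path, metadata_path: str | Path) -> PeakTable:
    """Load a peak table plus its sample metadata and validate both.

    Raises ``ValueError`` naming the offending sample/column on dimension
    mismatches, unknown group labels or duplicate sample IDs.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("mz", "rt"):
        if col not in df.columns:
            raise ValueError(f"peak table {path} lacks required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt")]
    if not sample_cols:
        raise ValueError(f"peak table {path} has no sample columns")

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path), dtype=str)
    for col in ("sample_id", "group", "experiment"):
        if col not in meta.columns:
            raise ValueError(f"metadata {metadata_path} lacks column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample ID {dup!r} in metadata")
    meta = meta.set_index("sample_id")
    for s in sample_cols:
        if s not in meta.index:
            raise ValueError(f"sample {s!r} absent from metadata")

    intensities = df[sample_cols].to_numpy(dtype=float)
    return PeakTable(
        mz=df["mz"].to_numpy(dtype=float),
        rt=df["rt"].to_numpy(dtype=float),
        intensities=intensities,
        sample_ids=sample_cols,
        groups=meta.loc[sample_cols, "group"].to_numpy(dtype=object),
        experiments=meta.loc[sample_cols, "experiment"].to_numpy(dtype=object),
    )


def write_peak_table(table: PeakTable, path: str | Path,
                     metadata_path: str | Path | None = None) -> None:
    """Write the intensity matrix (and optionally metadata) back to disk.

    Missing values are written as empty cells; m/z and RT keep full double
    precision.
    """
    path = Path(path)
    df = pd.DataFrame(table.intensities, columns=table.sample_ids)
    df.insert(0, "rt", table.rt)
    df.insert(0, "mz", table.mz)
    df.to_csv(path, sep=_sep_for(path), index=False, na_rep="",
              float_format="%.17g")
    if metadata_path is not None:
        write_metadata(table, metadata_path)


def write_metadata(table: PeakTable, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({
        "sample_id": table.sample_ids,
        "group": table.groups,
        "experiment": table.experiments,
    }).to_csv(path, sep=_sep_for(path), index=False)


def read_reference_library(path: str | Path) -> ReferenceLibrary:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str})
    for col in ("metabolite_id", "name", "neutral_mass"):
        if col not in df.columns:
            raise ValueError(f"library {path} lacks column {col!r}")
    return ReferenceLibrary(
        metabolite_ids=df["metabolite_id"].tolist(),
        names=df["name"].astype(str).tolist(),
        neutral_masses=df["neutral_mass"].to_numpy(dtype=float),
    )


def write_reference_library(lib: ReferenceLibrary, path: str | Path) -> None:
    pd.DataFrame({
        "metabolite_id": lib.metabolite_ids,
        "name": lib.names,
        "neutral_mass": lib.neutral_masses,
    }).to_csv(Path(path), sep="\t", index=False, float_format="%.17g")


def load_true_markers(path: str | Path | None = None) -> TrueMarkerSet:
    """Load a true-marker ID set; default is the packaged serum marker panel.

    The packaged panel lists 13 literature-validated HCC-vs-cirrhosis
    markers; the default set keeps the 12 applicable to serum data and
    drops the single urine-only entry.

    A custom file may be a headerless one-ID-per-line text file or a TSV
    whose first column holds the IDs.
    """
    if path is None:
        ref = importlib.resources.files("metastrat.data") / "true_markers.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
        serum = df[df["biofluid"].str.contains("Serum", case=False)]
        return TrueMarkerSet(frozenset(serum["metabolite_id"]))
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            ids.append(line.split("\t")[0].split(",")[0])
    if ids and ids[0].lower() in {"metabolite_id", "id"}:
        ids = ids[1:]
    if not ids:
        raise ValueError(f"true-marker file {path} is empty")
    return TrueMarkerSet(frozenset(ids))
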