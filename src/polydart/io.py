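"""Reading, writing and validation of DArT-style marker tables.

Two CSV dialects are supported, both with one row per marker and one column
per sample, preceded by metadata columns (``marker_id``, optionally
``chromosome`` and ``call_rate``):

* SilicoDArT — dominant presence/absence markers scored 1 (restriction
  fragment present) or 0 (absent);
* SNP — codominant markers scored 0 (reference-allele homozygote),
  1 (alternate-allele homozygote) or 2 (heterozygote).

Missing calls are represented by ``-`` or an empty cell on read and written
back as ``-``.  Call rates (fraction of samples with a non-missing score)
are always recomputed from the scores on read; a stored ``call_rate``
column is compared against the recomputed values and discrepancies are
logged, with the recomputed value winning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("polydart")

#: Canonical chromosome set of the hexaploid bread-wheat reference:
#: chromosomes 1..7 of the A, B and D subgenomes.
SUBGENOME_LETTERS = ("A", "B", "D")
CHROMOSOMES = tuple(f"{i}{g}" for g in SUBGENOME_LETTERS for i in range(1, 8))
UNASSIGNED = "unassigned"

#: Missing-call spellings accepted on read; the first is used on write.
DEFAULT_MISSING_CODES = ("-", "")

METADATA_COLUMNS = ("marker_id", "chromosome", "call_rate")


class DartIOError(ValueError):
    """Malformed marker table (bad scores, duplicate ids, sample mismatch)."""


class UnsupportedDialectError(DartIOError):
    """Two-row SNP export detected; only the one-row 0/1/2 dialect is read."""


def normalize_chromosome(label: object) -> str:
    """Map a chromosome label onto the canonical ``1A``..``7D`` set.

    Unknown or empty labels become ``"unassigned"`` (logged at WARNING, not
    an error, so partially mapped exports remain usable).
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return UNASSIGNED
    text = str(label).strip().upper()
    if text in CHROMOSOMES:
        return text
    if text in ("", "UNASSIGNED", "NA", "NAN", "-"):
        return UNASSIGNED
    logger.warning("unknown chromosome label %r mapped to 'unassigned'", label)
    return UNASSIGNED


# ---------------------------------------------------------------------------
# Sample panel
# ---------------------------------------------------------------------------

@dataclass
class SamplePanel:
    """Sample metadata: species, ploidy, reported genome formula and role.

    ``ploidy // 2`` is the expected number of constituent subgenomes of a
    species (1 for diploids, 2 for allotetraploids, 3 for allohexaploids).
    Roles are free-form tags; the pipeline recognises ``diploid_analyzer``,
    ``polyploid_target`` and ``reference``.
    """

    table: pd.DataFrame  # index: sample_id; columns: species, ploidy, genome_formula, role

    def __post_init__(self) -> None:
        required = {"species", "ploidy", "genome_formula", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise DartIOError(f"panel missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DartIOError(f"duplicate sample ids in panel: {dupes}")
        self.table = self.table.assign(ploidy=self.table["ploidy"].astype(int))
        bad = self.table.index[(self.table["ploidy"] < 2) | (self.table["ploidy"] % 2 != 0)]
        if len(bad):
            raise DartIOError(f"ploidy must be an even integer >= 2; offending samples: {list(bad)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SamplePanel":
        df = pd.read_csv(path, dtype={"sample_id": str, "species": str}, keep_default_na=False)
        if "sample_id" not in df.columns:
            raise DartIOError(f"{path}: panel CSV must have a 'sample_id' column")
        return cls(df.set_index("sample_id"))

    def to_csv(self, path: str | Path) -> None:
        self.table.rename_axis("sample_id").reset_index().to_csv(path, index=False)

    # -- lookups ------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        """Species names in panel order (first occurrence)."""
        return list(dict.fromkeys(self.table["species"]))

    def samples_of(self, species: str) -> list[str]:
        hits = self.table.index[self.table["species"] == species]
        if not len(hits):
            raise KeyError(f"species {species!r} not in panel")
        return list(hits)

    def ploidy_of(self, species: str) -> int:
        return int(self.table.loc[self.samples_of(species)[0], "ploidy"])

    def species_with_role(self, role: str) -> list[str]:
        sub = self.table[self.table["role"] == role]
        return list(dict.fromkeys(sub["species"]))

    def subgenome_count(self, species: str) -> int:
        return self.ploidy_of(species) // 2


# ---------------------------------------------------------------------------
# Score matrices
# ---------------------------------------------------------------------------

@dataclass
class _ScoreMatrix:
    """Markers x samples score matrix with per-marker metadata.

    ``scores`` is float-valued with NaN encoding a missing call; valid
    non-missing values are defined per subclass. ``call_rate`` is always
    consistent with ``scores`` (recomputed at construction).
    """

    scores: pd.DataFrame
    chromosome: pd.Series = None  # type: ignore[assignment]
    call_rate: pd.Series = field(init=False)

    VALID_SCORES = frozenset()  # class attribute, not a dataclass field
    KIND = "marker"

    def __post_init__(self) -> None:
        if not self.scores.index.is_unique:
            dupes = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise DartIOError(f"duplicate marker_id: {dupes[:5]}")
        values = self.scores.to_numpy(dtype=float)
        finite = values[~np.isnan(values)]
        bad = ~np.isin(finite, sorted(self.VALID_SCORES))
        if bad.any():
            rows, cols = np.nonzero(~np.isnan(values) & ~np.isin(values, sorted(self.VALID_SCORES)))
            r, c = rows[0], cols[0]
            raise DartIOError(
                f"invalid {self.KIND} score {values[r, c]:g} at marker "
                f"{self.scores.index[r]!r}, sample {self.scores.columns[c]!r}"
            )
        if self.chromosome is None:
            self.chromosome = pd.Series(UNASSIGNED, index=self.scores.index)
        else:
            self.chromosome = (
                self.chromosome.reindex(self.scores.index)
                .map(normalize_chromosome)
                .rename(None)
            )
        self.call_rate = self.scores.notna().sum(axis=1) / self.scores.shape[1]

    # -- basic shape --------------------------------------------------------

    @property
    def marker_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_markers(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    # -- operations ---------------------------------------------------------

    def filter_call_rate(self, threshold: float) -> "_ScoreMatrix":
        """Keep markers whose call rate is *strictly* greater than ``threshold``.

        Marker order is preserved. An empty result is allowed (logged).
        """
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"call-rate threshold must be in [0, 1], got {threshold}")
        keep = self.call_rate > threshold
        if not keep.any():
            logger.warning("call-rate filter at >%s removed every marker", threshold)
        return type(self)(self.scores.loc[keep], self.chromosome.loc[keep])

    def subset_markers(self, marker_ids: Iterable[str]) -> "_ScoreMatrix":
        idx = pd.Index(marker_ids)
        return type(self)(self.scores.loc[idx], self.chromosome.loc[idx])

    def to_csv(self, path: str | Path, missing_code: str = DEFAULT_MISSING_CODES[0]) -> None:
        out = self.scores.copy()
        formatted = out.map(lambda v: missing_code if pd.isna(v) else str(int(v)))
        formatted.insert(0, "chromosome", self.chromosome)
        formatted.insert(1, "call_rate", self.call_rate.map(lambda v: f"{v:.6g}"))
        formatted.rename_axis("marker_id").reset_index().to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        panel: SamplePanel,
        missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
    ) -> "_ScoreMatrix":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "marker_id" not in raw.columns:
            raise DartIOError(f"{path}: missing 'marker_id' column")
        sample_cols = [c for c in raw.columns if c not in METADATA_COLUMNS]
        if set(sample_cols) != set(panel.sample_ids):
            extra = sorted(set(sample_cols) - set(panel.sample_ids))
            absent = sorted(set(panel.sample_ids) - set(sample_cols))
            raise DartIOError(
                f"{path}: sample columns do not match panel "
                f"(unexpected: {extra}, missing: {absent})"
            )
        ids = raw["marker_id"]
        if ids.duplicated().any():
            counts = ids.value_counts()
            dupes = counts[counts > 1]
            if cls.KIND == "SNP" and (dupes == 2).all():
                raise UnsupportedDialectError(
                    f"{path}: every duplicated marker_id appears exactly twice — this "
                    "looks like a two-row SNP export; only the one-row 0/1/2 dialect "
                    "is supported"
                )
            raise DartIOError(f"{path}: duplicate marker_id: {list(dupes.index[:5])}")

        def parse_cell(value: str, marker: str, sample: str) -> float:
            text = value.strip()
            if text in missing_codes:
                return np.nan
            try:
                score = float(text)
            except ValueError:
                raise DartIOError(
                    f"{path}: non-numeric score {value!r} at marker {marker!r}, "
                    f"sample {sample!r}"
                ) from None
            if score not in cls.VALID_SCORES:
                raise DartIOError(
                    f"{path}: invalid {cls.KIND} score {value!r} at marker {marker!r}, "
                    f"sample {sample!r} (allowed: {sorted(cls.VALID_SCORES)})"
                )
            return score

        data = {}
        for sample in panel.sample_ids:  # panel order, not file order
            column = raw[sample]
            data[sample] = [
                parse_cell(v, m, sample) for v, m in zip(column, ids)
            ]
        scores = pd.DataFrame(data, index=pd.Index(ids, name="marker_id"), dtype=float)
        chrom = (
            raw.set_index("marker_id")["chromosome"]
            if "chromosome" in raw.columns
            else None
        )
        matrix = cls(scores, chrom)
        if "call_rate" in raw.columns:
            stored = pd.to_numeric(raw.set_index("marker_id")["call_rate"], errors="coerce")
            drift = (stored - matrix.call_rate).abs()
            n_off = int((drift > 1e-6).sum())
            if n_off:
                logger.info(
                    "%s: stored call_rate differs from recomputed for %d markers; "
                    "recomputed values used",
                    path,
                    n_off,
                )
        return matrix


class MarkerMatrix(_ScoreMatrix):
    """Dominant SilicoDArT presence/absence matrix (scores 0/1, NaN missing)."""

    VALID_SCORES = frozenset({0.0, 1.0})
    KIND = "SilicoDArT"


class SnpMatrix(_ScoreMatrix):
    """Codominant SNP matrix (scores 0/1/2, NaN missing)."""

    VALID_SCORES = frozenset({0.0, 1.0, 2.0})
    KIND = "SNP"


def read_silicodart(
    path: str | Path,
    panel: SamplePanel,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> MarkerMatrix:
    """Read a SilicoDArT presence/absence CSV against a sample panel."""
    return MarkerMatrix.read_csv(path, panel, missing_codes)


def read_snp(
    path: str | Path,
    panel: SamplePanel,
    missing_codes: Sequence[str] = DEFAULT_MISSING_CODES,
) -> SnpMatrix:
    """Read a one-row-per-marker SNP CSV (0/1/2 scores) against a panel."""
    return SnpMatrix.read_csv(path, panel, missing_codes)


def filter_call_rate(matrix: _ScoreMatrix, threshold: float) -> _ScoreMatrix:
    """Functional alias for :meth:`_ScoreMatrix.filter_call_rate`."""
    return matrix.filter_call_rate(threshold)
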