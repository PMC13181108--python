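"""Input/output for pooled-screen data.

Guide libraries, read-count matrices, screen designs and result tables are
exchanged as plain delimited text (TSV by default).  An optional exact-match
spacer counter turns raw sequencing reads into a count column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TARGETING = "targeting"
NON_TARGETING = "non_targeting"
SAFE_TARGETING = "safe_targeting"
CATEGORIES = (TARGETING, NON_TARGETING, SAFE_TARGETING)

TWO_SAMPLE_ROLES = ("low_bin", "high_bin")
FOUR_SAMPLE_ROLES = ("unstim_low", "unstim_high", "stim_low", "stim_high")


@dataclass(frozen=True)
class GuideLibrary:
    """Guide → gene / control-category map.

    ``table`` is indexed by unique ``guide_id`` and has columns ``category``
    (one of targeting / non_targeting / safe_targeting), ``gene`` (gene
    symbol for targeting guides, empty otherwise) and optionally ``spacer``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate guide_id(s): {dups[:5]}")
        bad_cat = set(t["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValueError(f"unknown guide categories: {sorted(bad_cat)}")
        targeting = t["category"] == TARGETING
        missing = targeting & (t["gene"].isna() | (t["gene"] == ""))
        if missing.any():
            raise ValueError(
                "targeting guides without a gene: "
                f"{t.index[missing][:5].tolist()}"
            )
        # control guides carry no gene label
        object.__setattr__(
            self, "table", t.assign(gene=t["gene"].where(targeting, ""))
        )

    @property
    def guide_ids(self) -> pd.Index:
        return self.table.index

    @property
    def is_control(self) -> pd.Series:
        return self.table["category"].isin([NON_TARGETING, SAFE_TARGETING])

    @property
    def control_ids(self) -> pd.Index:
        return self.table.index[self.is_control]

    @property
    def genes(self) -> list[str]:
        g = self.table.loc[self.table["category"] == TARGETING, "gene"]
        return sorted(g.unique())

    def category_counts(self) -> dict[str, int]:
        return self.table["category"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer read counts, guides × samples."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate guide ids in count matrix")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def align_to(self, library: GuideLibrary) -> "CountMatrix":
        """Reorder rows to the library's guide order.

        Guides present in the counts but absent from the library are a hard
        error (silent drops hide joins gone wrong); guides missing from the
        counts are also an error.
        """
        extra = self.guides.difference(library.guide_ids)
        if len(extra):
            raise ValueError(
                f"guides in counts but not in library: {extra[:5].tolist()}"
            )
        missing = library.guide_ids.difference(self.guides)
        if len(missing):
            raise ValueError(
                f"guides in library but not in counts: {missing[:5].tolist()}"
            )
        return CountMatrix(self.counts.loc[library.guide_ids])


@dataclass(frozen=True)
class ScreenDesign:
    """Sample-role assignment for a two- or four-sample sort screen.

    ``roles`` maps sample name → role.  Two-sample roles are ``low_bin`` /
    ``high_bin``; four-sample roles are ``unstim_low`` / ``unstim_high`` /
    ``stim_low`` / ``stim_high``.  ``sort_fraction`` is the proportion of
    cells gated into each bin (default 0.30, the top/bottom 30% gates).
    """

    mode: str
    roles: Mapping[str, str]
    sort_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.mode not in ("two_sample", "four_sample"):
            raise ValueError(f"unknown design mode {self.mode!r}")
        required = TWO_SAMPLE_ROLES if self.mode == "two_sample" else FOUR_SAMPLE_ROLES
        seen = list(self.roles.values())
        for role in required:
            if seen.count(role) != 1:
                raise ValueError(
                    f"role {role!r} must be assigned to exactly one sample"
                )
        extra = set(seen) - set(required)
        if extra:
            raise ValueError(f"unexpected roles for {self.mode}: {sorted(extra)}")
        if not 0.0 < self.sort_fraction < 0.5:
            raise ValueError("sort_fraction must lie in (0, 0.5)")

    def sample_for(self, role: str) -> str:
        for sample, r in self.roles.items():
            if r == role:
                return sample
        raise KeyError(role)

    @property
    def samples(self) -> list[str]:
        return list(self.roles)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_library(path: str | Path) -> GuideLibrary:
    """Read a guide library from a delimited table.

    Required columns: ``guide_id``, ``category``, ``gene`` (blank for
    controls); optional ``spacer``.
    """
    df = _read_table(path)
    required = {"guide_id", "category", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].fillna("")
    cols = ["category", "gene"] + (["spacer"] if "spacer" in df.columns else [])
    return GuideLibrary(df.set_index("guide_id")[cols])


def write_library(library: GuideLibrary, path: str | Path) -> None:
    library.table.to_csv(path, sep="\t", index_label="guide_id")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV: header row, first column guide_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="guide_id")


def read_design(path: str | Path) -> ScreenDesign:
    """Read a screen design from a YAML key/value file.

    Expected keys: ``mode``, ``roles`` (sample → role map) and optionally
    ``sort_fraction``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ScreenDesign(
        mode=cfg["mode"],
        roles=dict(cfg["roles"]),
        sort_fraction=float(cfg.get("sort_fraction", 0.30)),
    )


def write_design(design: ScreenDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "mode": design.mode,
                "roles": dict(design.roles),
                "sort_fraction": design.sort_fraction,
            },
            fh,
        )


RESULT_FLOAT_FORMAT = "%.10g"


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a guide- or gene-level score table as TSV.

    The first column is the row identifier (guide or gene); all numeric
    columns are written with enough digits to round-trip through
    ``read_results`` at full float precision for realistic magnitudes.
    """
    table.to_csv(path, sep="\t", index_label=table.index.name or "id",
                 float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: %.17g written floats come back bit-identical
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


# ---------------------------------------------------------------------------
# exact-spacer counting


def _read_sequences(reads: str | Path | Iterable) -> list[str]:
    """Accept a FASTQ/FASTA path or an iterable of sequence strings/records."""
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        path = Path(reads)
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta") else "fastq"
        return [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
    out = []
    for r in reads:
        out.append(str(getattr(r, "seq", r)))
    return out


def count_spacers(
    reads: str | Path | Iterable,
    library: GuideLibrary,
    match_window: tuple[int, int] | None = None,
) -> tuple[pd.Series, int]:
    """Count exact spacer occurrences in raw reads.

    Each read is assigned to the first guide whose spacer occurs verbatim at
    an offset inside ``match_window`` (``None`` = anywhere in the read).
    Returns ``(counts, n_unmatched)`` with one count per library guide.
    No fuzzy matching: a one-mismatch read is unmatched by design.
    """
    if "spacer" not in library.table.columns:
        raise ValueError("library has no spacer column")
    spacers = library.table["spacer"].astype(str)
    lengths = spacers.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"spacers must have equal length, got lengths {sorted(lengths)}")
    k = int(lengths[0])

    seqs = _read_sequences(reads)
    if not seqs:
        warnings.warn("empty read set: returning all-zero counts")
    spacer_to_guide = {}
    for gid, sp in spacers.items():
        spacer_to_guide.setdefault(sp, gid)

    counts = pd.Series(0, index=library.guide_ids, dtype=np.int64)
    unmatched = 0
    for seq in seqs:
        if match_window is None:
            lo, hi = 0, max(len(seq) - k, 0)
        else:
            lo, hi = match_window
            hi = min(hi, len(seq) - k)
        hit = None
        for off in range(lo, hi + 1):
            gid = spacer_to_guide.get(seq[off : off + k])
            if gid is not None:
                hit = gid
                break
        if hit is None:
            unmatched += 1
        else:
            counts[hit] += 1
    return counts, unmatched
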