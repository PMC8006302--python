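"""AIRR rearrangement tables, the repertoire data model, and quality filters.

The unit record is a single annotated V(D)J rearrangement: subject, chain,
V/J gene calls, the CDR3 amino-acid sequence and (where known) the isotype.
Repertoires are held as one flat :class:`pandas.DataFrame` plus a
subject -> cohort label map, which keeps vectorised group-by operations
cheap for the clustering and feature stages.

Tables are read and written as AIRR/MiAIRR-style TSV (``v_call``,
``j_call``, ``junction_aa`` column names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: isotypes retained by the quality filter (naive compartment)
NAIVE_ISOTYPES = frozenset({"IgM", "IgD"})

KNOWN_ISOTYPES = frozenset({"IgM", "IgD", "IgA", "IgG", "IgE", "unknown"})

CASE, CONTROL = "case", "control"

#: columns every input table must provide
REQUIRED_COLUMNS = ("sequence_id", "subject_id", "v_call", "j_call")

#: canonical column order used when writing
AIRR_COLUMNS = (
    "sequence_id",
    "subject_id",
    "chain",
    "v_call",
    "j_call",
    "junction_aa",
    "junction_length",
    "cdr3_aa",
    "isotype",
)


class FormatError(ValueError):
    """Input table violates the expected AIRR layout."""


class LabelingError(ValueError):
    """A subject in the table has no cohort label."""


@dataclass
class RepertoireSet:
    """A cohort of per-subject rearrangement collections.

    Parameters
    ----------
    df
        One row per rearrangement; must contain at least the columns in
        :data:`REQUIRED_COLUMNS` plus ``cdr3_aa``. Extra columns are kept
        as opaque annotations.
    labels
        Map ``subject_id -> 'case' | 'control'`` covering every subject
        in ``df``.
    """

    df: pd.DataFrame
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in (*REQUIRED_COLUMNS, "cdr3_aa") if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        present = set(self.df["subject_id"].unique())
        unlabeled = present - set(self.labels)
        if unlabeled:
            raise LabelingError(
                f"subjects without a cohort label: {sorted(unlabeled)[:5]}"
            )
        bad = set(self.labels.values()) - {CASE, CONTROL}
        if bad:
            raise LabelingError(f"labels must be 'case'/'control', got {sorted(bad)}")
        cdr3 = self.df["cdr3_aa"]
        if len(cdr3) and (
            cdr3.isna().any()
            or not cdr3.str.fullmatch(f"[{AA_ALPHABET}]+").all()
        ):
            raise FormatError("cdr3_aa must be non-empty over the 20 standard AAs")

    # -- convenience views -------------------------------------------------
    @property
    def subjects(self) -> list:
        """Subject ids, in label-map order restricted to subjects present."""
        present = set(self.df["subject_id"].unique())
        return [s for s in self.labels if s in present]

    @property
    def n_sequences(self) -> int:
        return len(self.df)

    def label_series(self) -> pd.Series:
        return pd.Series({s: self.labels[s] for s in self.subjects}, name="label")

    def subject_counts(self) -> pd.Series:
        return self.df["subject_id"].value_counts()

    def subset(self, subject_ids) -> "RepertoireSet":
        keep = set(subject_ids)
        sub = self.df[self.df["subject_id"].isin(keep)].copy()
        return RepertoireSet(sub, {s: self.labels[s] for s in self.labels if s in keep})

    def equals(self, other: "RepertoireSet") -> bool:
        if self.labels != other.labels:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        return a.equals(b)


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`apply_exclusion_filters`."""

    n_input: int = 0
    removed_frame: int = 0        # rule (a): junction nt length not divisible by 3
    removed_isotype: int = 0      # rule (b): isotype outside IgM/IgD
    removed_low_depth: int = 0    # rule (c): sequences of under-sampled subjects
    dropped_subjects: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["a_frame", "b_isotype", "c_depth"],
                "removed": [self.removed_frame, self.removed_isotype, self.removed_low_depth],
            }
        )


def read_airr(path, label_map: dict, strip_junction_flanks: bool = True) -> RepertoireSet:
    """Load an AIRR rearrangement TSV into a :class:`RepertoireSet`.

    ``cdr3_aa`` is taken from a ``cdr3_aa`` column when present; otherwise
    it is derived from ``junction_aa`` by stripping the two flanking
    conserved residues (104-Cys / 118-Trp-or-Phe) when
    ``strip_junction_flanks`` is true, else the junction is used verbatim.
    Unknown columns are preserved; row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if "cdr3_aa" not in df.columns and "junction_aa" not in df.columns:
        missing.append("junction_aa")
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if "cdr3_aa" not in df.columns:
        junc = df["junction_aa"]
        df["cdr3_aa"] = junc.str.slice(1, -1) if strip_junction_flanks else junc
    if "chain" not in df.columns:
        df["chain"] = "heavy"
    if "isotype" not in df.columns:
        df["isotype"] = "unknown"
    if "junction_length" in df.columns:
        df["junction_length"] = pd.to_numeric(df["junction_length"], errors="coerce")
    return RepertoireSet(df, dict(label_map))


def write_airr(reps: RepertoireSet, path) -> None:
    """Write the repertoire as an AIRR-style TSV (sorted canonical columns first)."""
    df = reps.df.copy()
    if "junction_aa" not in df.columns:
        df["junction_aa"] = "C" + df["cdr3_aa"] + "W"
    if "junction_length" not in df.columns:
        df["junction_length"] = 3 * df["junction_aa"].str.len()
    cols = [c for c in AIRR_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def write_labels(reps: RepertoireSet, path) -> None:
    pd.Series(reps.labels, name="label").rename_axis("subject_id").to_csv(path, sep="\t")


def read_labels(path) -> dict:
    s = pd.read_csv(path, sep="\t", index_col="subject_id")["label"]
    return s.to_dict()


def apply_exclusion_filters(
    reps: RepertoireSet,
    min_depth: int = 2000,
    keep_unknown_isotype: bool = False,
) -> tuple[RepertoireSet, FilterReport]:
    """Apply the three repertoire quality filters, in order.

    (a) drop rearrangements whose junction nucleotide length is not a
        multiple of three (untranslatable); skipped with a warning when the
        table carries no ``junction_length``;
    (b) drop rearrangements with an isotype other than IgM/IgD (records
        with unknown isotype are dropped too unless ``keep_unknown_isotype``,
        which accommodates tables that never recorded isotype);
    (c) drop whole subjects whose retained depth after (a)+(b) falls below
        ``min_depth`` rearrangements.

    Depth is counted on retained rearrangement records. The operation is
    idempotent. An empty result is legal.
    """
    report = FilterReport(n_input=len(reps.df))
    df = reps.df

    if "junction_length" in df.columns and df["junction_length"].notna().all():
        keep = (df["junction_length"].astype(int) % 3) == 0
        report.removed_frame = int((~keep).sum())
        df = df[keep]
    else:
        report.warnings.append(
            "junction_length absent or incomplete; frame filter (a) skipped"
        )

    iso = df["isotype"] if "isotype" in df.columns else pd.Series("unknown", index=df.index)
    ok = iso.isin(NAIVE_ISOTYPES)
    if keep_unknown_isotype:
        ok |= iso.eq("unknown")
    report.removed_isotype = int((~ok).sum())
    df = df[ok]

    depth = df["subject_id"].value_counts()
    shallow = set(depth[depth < min_depth].index)
    # subjects with zero surviving records are also "dropped"
    shallow |= set(reps.labels) - set(depth.index)
    report.dropped_subjects = sorted(shallow)
    report.removed_low_depth = int(df["subject_id"].isin(shallow).sum())
    df = df[~df["subject_id"].isin(shallow)]

    report.n_output = len(df)
    labels = {s: l for s, l in reps.labels.items() if s not in shallow}
    return RepertoireSet(df.copy(), labels), report
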