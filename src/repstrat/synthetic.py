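"""Two-cohort synthetic naive BCR repertoires with planted, recoverable signal.

The generator emulates a balanced case/control study of annotated naive
B-cell receptor rearrangements: per-subject repertoires with Zipf-like
V/J gene usage, near-normal CDR3 length distribution (truncated to 5-30
amino acids) and uniform background CDR3 composition. Disease signal is
planted as cohort-biased clonal clusters: each planted cluster is grown
from a random seed CDR3 by per-position substitution, and its members are
distributed across subjects with a configurable cohort bias (purity).
An optional motif specification embeds a conjoint-triad-class 3-mer in
every planted seed so that triad-level enrichment is recoverable too.

Ground truth (which V/J/seed each planted cluster used, which cohort it
favours, which sequence ids belong to it) is returned separately and is
never written into the rearrangement table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import CT_CLASSES
from .io import AA_ALPHABET, CASE, CONTROL, RepertoireSet

AA = np.array(list(AA_ALPHABET))


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def default_v_pool(chain: str = "heavy") -> tuple[tuple[str, ...], np.ndarray]:
    """~50 IMGT-style heavy V names (30 for light) with Zipf-like usage."""
    if chain == "heavy":
        names = tuple(
            f"IGHV{fam}-{num}*01" for fam, count in ((3, 12), (1, 10), (4, 8), (2, 6), (5, 6), (6, 4), (7, 4)) for num in range(1, count + 1)
        )
    else:
        names = tuple(f"IGKV{fam}-{num}*01" for fam in range(1, 6) for num in range(1, 7))
    return names, _zipf_weights(len(names), 1.0)


def default_j_pool(chain: str = "heavy") -> tuple[tuple[str, ...], np.ndarray]:
    n = 6 if chain == "heavy" else 5
    prefix = "IGHJ" if chain == "heavy" else "IGKJ"
    return tuple(f"{prefix}{i}*01" for i in range(1, n + 1)), _zipf_weights(n, 1.5)


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """Bias planted seed CDR3s toward a conjoint-triad class.

    Each planted cluster seed receives ``triads_per_seed`` embedded 3-mers
    whose residues are drawn uniformly from the given CT class.
    """

    ct_class: int = 3
    triads_per_seed: int = 1


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_case: int = 48
    n_control: int = 44
    seqs_per_subject: int = 2000
    chain_set: tuple = ("heavy",)
    v_gene_pool: tuple | None = None   # (names, weights); default per chain
    j_gene_pool: tuple | None = None
    cdr3_length_mean: float = 15.0
    cdr3_length_sd: float = 3.0
    n_planted_clusters: int = 10
    planted_purity: float = 0.9
    planted_mutation_rate: float = 0.03
    planted_cluster_size: int = 100    # sequences per planted cluster
    motif_spec: MotifSpec | None = None
    isotype_probs: tuple = (("IgM", 0.7), ("IgD", 0.3))
    seed: int = 0

    def __post_init__(self):
        for name in ("n_case", "n_control", "seqs_per_subject", "planted_cluster_size"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be positive")
        if self.n_planted_clusters < 0:
            raise InvalidConfigError("n_planted_clusters must be >= 0")
        if self.cdr3_length_mean < 5:
            raise InvalidConfigError("cdr3_length_mean must be >= 5")
        if not (0.5 <= self.planted_purity <= 1.0):
            raise InvalidConfigError("planted_purity must lie in [0.5, 1]")
        if not (0.0 <= self.planted_mutation_rate < 1.0):
            raise InvalidConfigError("planted_mutation_rate must lie in [0, 1)")
        if not set(self.chain_set) <= {"heavy", "light"}:
            raise InvalidConfigError("chain_set must be a subset of {heavy, light}")
        for pool in (self.v_gene_pool, self.j_gene_pool):
            if pool is not None and abs(sum(pool[1]) - 1.0) > 1e-8:
                raise InvalidConfigError("gene pool weights must sum to 1")
        if self.motif_spec is not None and self.motif_spec.ct_class not in CT_CLASSES:
            raise InvalidConfigError("motif_spec.ct_class must be in 1..7")


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping, kept apart from the AIRR table."""

    #: one row per planted cluster: chain, v_gene, j_gene, cdr3_length,
    #: seed_cdr3, biased_label
    table: pd.DataFrame
    #: planted cluster index -> list of sequence_ids belonging to it
    members: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        tab = self.table.copy()
        tab["sequence_ids"] = [",".join(self.members.get(i, [])) for i in tab.index]
        tab.to_csv(path, sep="\t", index=True, index_label="planted_cluster")


def _truncated_normal_lengths(rng, n, mean, sd, low=5, high=30) -> np.ndarray:
    """Rounded normal draws, redrawing values outside [low, high]."""
    out = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(int)
        bad = (out < low) | (out > high)
    return out


def _random_cdr3s(rng, lengths) -> list:
    total = int(lengths.sum())
    letters = AA[rng.integers(0, 20, size=total)]
    seqs, pos = [], 0
    for L in lengths:
        seqs.append("".join(letters[pos : pos + L]))
        pos += L
    return seqs


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        choices = [a for a in AA_ALPHABET if a != chars[i]]
        chars[i] = choices[rng.integers(0, 19)]
    return "".join(chars)


def generate_repertoires(config: SimConfig) -> tuple[RepertoireSet, GroundTruth]:
    """Draw a two-cohort repertoire set plus its planted-signal ground truth.

    Background rearrangements are uniform random CDR3s; planted clusters
    are seed CDR3s mutated at ``planted_mutation_rate`` whose members
    replace randomly chosen background rows of subjects drawn with cohort
    bias ``planted_purity`` (even-indexed planted clusters favour cases,
    odd-indexed favour controls). Identical config (including seed) gives
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    case_ids = [f"case_{i+1:03d}" for i in range(config.n_case)]
    ctrl_ids = [f"ctrl_{i+1:03d}" for i in range(config.n_control)]
    labels = {**{s: CASE for s in case_ids}, **{s: CONTROL for s in ctrl_ids}}
    subjects = case_ids + ctrl_ids

    iso_names = [n for n, _ in config.isotype_probs]
    iso_p = np.array([p for _, p in config.isotype_probs], dtype=float)
    iso_p = iso_p / iso_p.sum()

    frames = []
    truth_rows = []
    truth_members: dict[int, list] = {}
    planted_idx = 0
    for chain in config.chain_set:
        v_names, v_w = config.v_gene_pool or default_v_pool(chain)
        j_names, j_w = config.j_gene_pool or default_j_pool(chain)
        n_total = len(subjects) * config.seqs_per_subject
        lengths = _truncated_normal_lengths(
            rng, n_total, config.cdr3_length_mean, config.cdr3_length_sd
        )
        df = pd.DataFrame(
            {
                "subject_id": np.repeat(subjects, config.seqs_per_subject),
                "chain": chain,
                "v_call": rng.choice(v_names, size=n_total, p=np.asarray(v_w, float)),
                "j_call": rng.choice(j_names, size=n_total, p=np.asarray(j_w, float)),
                "cdr3_aa": _random_cdr3s(rng, lengths),
                "isotype": rng.choice(iso_names, size=n_total, p=iso_p),
            }
        )
        df["sequence_id"] = [f"{chain[0]}seq_{i:07d}" for i in range(n_total)]

        # plant cohort-biased clusters by overwriting background rows;
        # rows are contiguous per subject, so draw offsets directly
        row_start = {s: i * config.seqs_per_subject for i, s in enumerate(subjects)}
        used_rows: set = set()
        for c in range(config.n_planted_clusters):
            biased = CASE if c % 2 == 0 else CONTROL
            pool, other = (case_ids, ctrl_ids) if biased == CASE else (ctrl_ids, case_ids)
            v = v_names[rng.integers(0, len(v_names))]
            j = j_names[rng.integers(0, len(j_names))]
            L = int(
                _truncated_normal_lengths(
                    rng, 1, config.cdr3_length_mean, config.cdr3_length_sd
                )[0]
            )
            seed_cdr3 = "".join(AA[rng.integers(0, 20, size=L)])
            if config.motif_spec is not None:
                cls = CT_CLASSES[config.motif_spec.ct_class]
                for _ in range(config.motif_spec.triads_per_seed):
                    start = int(rng.integers(1, max(L - 3, 2)))
                    triad = "".join(
                        cls[rng.integers(0, len(cls))] for _ in range(3)
                    )
                    seed_cdr3 = seed_cdr3[:start] + triad + seed_cdr3[start + 3 :]
            member_ids = []
            for _ in range(config.planted_cluster_size):
                cohort = pool if rng.random() < config.planted_purity else other
                subj = cohort[rng.integers(0, len(cohort))]
                cdr3 = _mutate(rng, seed_cdr3, config.planted_mutation_rate)
                # overwrite one random, not-yet-planted row of that subject
                row = row_start[subj] + int(rng.integers(0, config.seqs_per_subject))
                while row in used_rows:
                    row = row_start[subj] + int(rng.integers(0, config.seqs_per_subject))
                used_rows.add(row)
                df.loc[row, ["v_call", "j_call", "cdr3_aa"]] = [v, j, cdr3]
                member_ids.append(df.at[row, "sequence_id"])
            truth_rows.append(
                {
                    "chain": chain,
                    "v_gene": v.split("*")[0],
                    "j_gene": j.split("*")[0],
                    "cdr3_length": L,
                    "seed_cdr3": seed_cdr3,
                    "biased_label": biased,
                }
            )
            truth_members[planted_idx] = member_ids
            planted_idx += 1
        df["junction_aa"] = "C" + df["cdr3_aa"] + "W"
        df["junction_length"] = 3 * df["junction_aa"].str.len()
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    cols = [
        "sequence_id", "subject_id", "chain", "v_call", "j_call",
        "junction_aa", "junction_length", "cdr3_aa", "isotype",
    ]
    reps = RepertoireSet(out[cols], labels)
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows),
        members=truth_members,
    )
    return reps, truth


def plant_ct_depletion(
    reps: RepertoireSet,
    truth: GroundTruth,
    triad_class: int,
    depletion_factor: float,
    seed: int = 0,
) -> RepertoireSet:
    """Deplete a conjoint-triad-class 3-mer from case-biased planted clusters.

    Every CDR3 belonging to a case-biased planted cluster is rescanned
    left to right; each 3-mer whose three residues all map to
    ``triad_class`` is kept with probability ``depletion_factor`` and
    otherwise destroyed by substituting its middle residue with a random
    residue outside the class. The expected surviving frequency of the
    targeted triad in the case set is therefore ~``depletion_factor``
    times the original. Control-biased clusters and background sequences
    are untouched.
    """
    if triad_class not in CT_CLASSES:
        raise ValueError("triad_class must be in 1..7")
    if not (0.0 < depletion_factor <= 1.0):
        raise ValueError("depletion_factor must lie in (0, 1]")
    if reps.df.empty:
        return RepertoireSet(reps.df.copy(), dict(reps.labels))
    rng = np.random.default_rng(seed)
    cls = set(CT_CLASSES[triad_class])
    non_cls = [a for a in AA_ALPHABET if a not in cls]

    case_rows = truth.table.index[truth.table["biased_label"] == CASE]
    target_ids = set()
    for i in case_rows:
        target_ids.update(truth.members.get(i, []))

    df = reps.df.copy()
    if depletion_factor == 1.0:
        return RepertoireSet(df, dict(reps.labels))
    mask = df["sequence_id"].isin(target_ids)
    new = {}
    for idx, seq in df.loc[mask, "cdr3_aa"].items():
        chars = list(seq)
        i = 0
        while i <= len(chars) - 3:
            if all(c in cls for c in chars[i : i + 3]):
                if rng.random() > depletion_factor:
                    chars[i + 1] = non_cls[rng.integers(0, len(non_cls))]
            i += 1
        new[idx] = "".join(chars)
    df.loc[mask, "cdr3_aa"] = pd.Series(new)
    df.loc[mask, "junction_aa"] = "C" + df.loc[mask, "cdr3_aa"] + "W"
    return RepertoireSet(df, dict(reps.labels))
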