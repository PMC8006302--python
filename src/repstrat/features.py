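"""Repertoire feature representations beyond similarity clusters.

Two families are provided:

* annotation frequencies — per-subject V-gene usage, J-gene usage, V-J
  pair usage, CDR3-length histogram and isotype usage, each normalised to
  sum to 1 per subject within its family;
* biophysicochemical CDR3 k-mer features — every CDR3 is decomposed into
  overlapping amino-acid k-mers and each residue is encoded by the five
  Atchley factors (polarity, secondary-structure propensity, molecular
  size, codon diversity, electrostatic charge).
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .io import RepertoireSet

# Atchley et al. (2005) factor scores: five orthogonal summaries of ~500
# amino-acid property scales, transcribed verbatim from the published
# table (factor I..V per residue).  Each factor has mean 0 over the 20
# residues; the factors are not rescaled here.
ATCHLEY_FACTORS: dict[str, tuple[float, ...]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

FACTOR_NAMES = ("polarity", "secondary_structure", "size", "codon_diversity", "charge")

#: sha256 of the canonical serialisation of the table, to guard against
#: accidental edits of the transcribed constants
ATCHLEY_SHA256 = "5b590e3c8b3ec2bf0937912de322ebb172ee1df8f446d299579e93765cb09283"


def atchley_checksum() -> str:
    text = ";".join(
        f"{aa}:" + ",".join(f"{v:.3f}" for v in ATCHLEY_FACTORS[aa])
        for aa in sorted(ATCHLEY_FACTORS)
    )
    return hashlib.sha256(text.encode()).hexdigest()


def verify_atchley_table() -> None:
    """Raise if the packaged Atchley constants were altered."""
    if atchley_checksum() != ATCHLEY_SHA256:
        raise RuntimeError("Atchley factor table failed its integrity checksum")


# 20 x 5 matrix indexed by byte value for vectorised encoding
_FACTOR_MATRIX = np.full((256, 5), np.nan)
for _aa, _row in ATCHLEY_FACTORS.items():
    _FACTOR_MATRIX[ord(_aa)] = _row


def cdr3_kmers(cdr3_aa: str, k: int) -> list[tuple[str, int]]:
    """All contiguous k-mers of a CDR3 with their 0-based start positions.

    Returns an empty list when the sequence is shorter than ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return [(cdr3_aa[i : i + k], i) for i in range(len(cdr3_aa) - k + 1)]


def atchley_encode(kmer: str) -> np.ndarray:
    """Encode a k-mer as the concatenation of per-residue factor vectors.

    The result has ``5 * len(kmer)`` values, residue-major (the first five
    values describe the first residue).
    """
    for aa in kmer:
        if aa not in ATCHLEY_FACTORS:
            raise KeyError(f"unknown residue {aa!r} (not a standard amino acid)")
    codes = np.frombuffer(kmer.encode("ascii"), dtype=np.uint8)
    return _FACTOR_MATRIX[codes].ravel()


def _encode_all_kmers(cdr3s: pd.Series, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised encoding of every k-mer of every CDR3.

    Returns ``(X, owner)`` where ``X`` is (n_kmers, 5k) and ``owner`` maps
    each k-mer row back to the positional index of its CDR3.
    """
    lengths = cdr3s.str.len().to_numpy()
    counts = np.maximum(lengths - k + 1, 0)
    blob = np.frombuffer("".join(cdr3s).encode("ascii"), dtype=np.uint8)
    starts = np.repeat(np.cumsum(lengths) - lengths, counts)
    offsets = np.concatenate([np.arange(c) for c in counts]) if len(counts) else np.array([], int)
    idx = (starts + offsets)[:, None] + np.arange(k)[None, :]
    codes = blob[idx] if len(idx) else np.empty((0, k), np.uint8)
    X = _FACTOR_MATRIX[codes].reshape(len(codes), 5 * k)
    owner = np.repeat(np.arange(len(cdr3s)), counts)
    return X, owner


def atchley_repertoire_features(reps: RepertoireSet, k: int = 3) -> pd.DataFrame:
    """Per-subject summary of Atchley-encoded CDR3 k-mers.

    For each subject, every CDR3 is decomposed into overlapping k-mers and
    encoded; the feature row is the mean and standard deviation of each of
    the ``5*k`` encoded positions over all of the subject's k-mers.
    Subjects whose sequences yield no k-mer at all are an error.
    """
    rows = {}
    for subject, grp in reps.df.groupby("subject_id", sort=False):
        X, _ = _encode_all_kmers(grp["cdr3_aa"], k)
        if len(X) == 0:
            raise ValueError(f"subject {subject!r} has no CDR3 k-mer of length {k}")
        rows[subject] = np.concatenate([X.mean(axis=0), X.std(axis=0)])
    names = [
        f"{stat}_p{pos}_{fac}"
        for stat in ("mean", "sd")
        for pos in range(k)
        for fac in FACTOR_NAMES
    ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return out.loc[[s for s in reps.subjects if s in out.index]]


def annotation_features(reps: RepertoireSet) -> pd.DataFrame:
    """Per-subject annotation frequency features.

    Families: V usage (``v:``), J usage (``j:``), V-J pair usage (``vj:``),
    CDR3 length histogram (``len:``), isotype usage (``iso:``). Each
    family's values sum to 1 per subject; genes unseen in a subject get 0.
    """
    if reps.df.empty:
        raise ValueError("empty repertoire set")
    df = reps.df.copy()
    df["v_gene"] = strip_allele(df["v_call"])
    df["j_gene"] = strip_allele(df["j_call"])
    df["vj"] = df["v_gene"] + "_" + df["j_gene"]
    df["cdr3_len"] = df["cdr3_aa"].str.len().astype(str)
    if "isotype" not in df.columns:
        df["isotype"] = "unknown"

    blocks = []
    for prefix, col in [("v", "v_gene"), ("j", "j_gene"), ("vj", "vj"),
                        ("len", "cdr3_len"), ("iso", "isotype")]:
        tab = pd.crosstab(df["subject_id"], df[col], normalize="index")
        tab.columns = [f"{prefix}:{c}" for c in tab.columns]
        blocks.append(tab)
    out = pd.concat(blocks, axis=1).fillna(0.0)
    return out.loc[[s for s in reps.subjects if s in out.index]]


def strip_allele(calls: pd.Series | str):
    """Reduce IMGT-style gene calls to the gene level.

    Takes the first call of a comma-separated multi-call and drops the
    ``*NN`` allele suffix (``"IGHV3-23*01,IGHV3-23*04" -> "IGHV3-23"``).
    """
    if isinstance(calls, str):
        return calls.split(",")[0].split("*")[0].strip()
    return calls.str.split(",").str[0].str.split("*").str[0].str.strip()
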