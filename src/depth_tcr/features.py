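"""Fixed-shape numeric featurization of HLA alleles and TCRs.

An HLA allele is represented by its pseudo sequence: the fixed subset of
amino-acid positions that contact the peptide/TCR (34 positions for class I
in the NetMHC-style convention; the tables are user-supplied so any
convention drops in).  A TCR beta chain is represented by the germline
CDR1/CDR2/CDR2.5 loops looked up from its V gene plus the hypervariable
CDR3, padded to length 27 by anchoring both ends and filling the middle
with ``'.'``.  Residues are encoded per-position with one of three schemes
(one-hot, scaled BLOSUM62 rows, Atchley factors); the pad character always
maps to the zero vector.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_CHAR = "."
CDR3_MAX_LEN = 27

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

__all__ = [
    "AMINO_ACIDS", "PAD_CHAR", "CDR3_MAX_LEN",
    "pad_cdr3", "strip_cdr3", "encoding_dim", "encode_sequence",
    "load_pseudo_table", "load_vcdr_table", "lookup_v_gene_cdrs",
    "TCRFeatures", "EncodedPair", "EncodedDataset",
    "encode_pair", "encode_pairs", "blosum62_matrix",
]


def _check_alphabet(seq: str, allow_pad: bool = False) -> None:
    allowed = set(AMINO_ACIDS) | ({PAD_CHAR} if allow_pad else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"invalid residue(s) {sorted(bad)} in sequence {seq!r}; "
            f"only the 20 standard amino acids are accepted"
        )


def pad_cdr3(cdr3: str, length: int = CDR3_MAX_LEN) -> str:
    """Pad a CDR3 to fixed length by anchoring both ends.

    The first ``ceil(L/2)`` residues stay left-anchored, the remaining
    ``floor(L/2)`` right-anchored, and ``'.'`` fills the middle, so the
    conserved C/F termini and the residues nearest them keep fixed
    positions regardless of loop length.
    """
    if not 1 <= len(cdr3) <= length:
        raise ValueError(f"CDR3 length {len(cdr3)} outside [1, {length}]")
    _check_alphabet(cdr3)
    left = (len(cdr3) + 1) // 2
    return cdr3[:left] + PAD_CHAR * (length - len(cdr3)) + cdr3[left:]


def strip_cdr3(padded: str) -> str:
    """Inverse of :func:`pad_cdr3`: drop the pad characters."""
    return padded.replace(PAD_CHAR, "")


def blosum62_matrix() -> pd.DataFrame:
    """BLOSUM62 restricted to the 20 standard residues."""
    m = substitution_matrices.load("BLOSUM62")
    data = [[float(m[a, b]) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
    return pd.DataFrame(data, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))


# Atchley's five physicochemical factors (standardized scores) per residue:
# I polarity/hydrophobicity, II secondary structure, III molecular size,
# IV codon composition, V electrostatic charge.
_ATCHLEY = {
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


def _encoder_table(scheme: str) -> np.ndarray:
    """Rows = residues in AMINO_ACIDS order plus a final all-zero pad row."""
    if scheme == "one_hot":
        table = np.eye(20, dtype=np.float32)
    elif scheme == "blosum62":
        b = blosum62_matrix().to_numpy(dtype=np.float32)
        table = b / np.abs(b).max()  # scale rows into [-1, 1]
    elif scheme == "atchley":
        table = np.array([_ATCHLEY[a] for a in AMINO_ACIDS], dtype=np.float32)
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}; "
                         "choose one_hot, blosum62 or atchley")
    return np.vstack([table, np.zeros((1, table.shape[1]), dtype=np.float32)])


def encoding_dim(scheme: str) -> int:
    """Channels per residue for the given scheme."""
    return _encoder_table(scheme).shape[1]


def encode_sequence(seq: str, scheme: str = "one_hot") -> np.ndarray:
    """Encode a sequence as a (positions x channels) float matrix.

    The pad character ``'.'`` encodes as the zero vector in every scheme.
    """
    table = _encoder_table(scheme)
    pad_row = table.shape[0] - 1
    idx = np.empty(len(seq), dtype=np.intp)
    for i, ch in enumerate(seq):
        if ch == PAD_CHAR:
            idx[i] = pad_row
        else:
            j = _AA_INDEX.get(ch)
            if j is None:
                raise ValueError(f"invalid residue {ch!r} in {seq!r}")
            idx[i] = j
    return table[idx]


def _read_table(source, columns: list[str]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"table is missing column(s) {sorted(missing)}")
    return df[columns]


def load_pseudo_table(source: str | Path | io.IOBase | pd.DataFrame) -> pd.DataFrame:
    """Load and validate an allele -> pseudo-sequence table (TSV or frame).

    All pseudo sequences must share one length and use only the 20 standard
    residues; duplicate allele rows are rejected.
    """
    df = _read_table(source, ["allele", "pseudo_seq"])
    if df["allele"].duplicated().any():
        dups = df.loc[df["allele"].duplicated(), "allele"].tolist()
        raise ValueError(f"duplicate allele rows: {dups}")
    lengths = df["pseudo_seq"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"pseudo sequences have mixed lengths {sorted(lengths)}")
    for s in df["pseudo_seq"]:
        _check_alphabet(s)
    return df.reset_index(drop=True)


def load_vcdr_table(source: str | Path | io.IOBase | pd.DataFrame) -> pd.DataFrame:
    """Load and validate the V gene -> CDR1/CDR2/CDR2.5 lookup table."""
    df = _read_table(source, ["v_gene", "cdr1", "cdr2", "cdr2_5"])
    if df["v_gene"].duplicated().any():
        dups = df.loc[df["v_gene"].duplicated(), "v_gene"].tolist()
        raise ValueError(f"duplicate V-gene rows: {dups}")
    for col in ("cdr1", "cdr2", "cdr2_5"):
        lengths = df[col].str.len().unique()
        if len(lengths) != 1:
            raise ValueError(f"{col} strings have mixed lengths {sorted(lengths)}")
        for s in df[col]:
            _check_alphabet(s)
    return df.reset_index(drop=True)


def lookup_v_gene_cdrs(v_gene: str, vcdr_table: pd.DataFrame) -> tuple[str, str, str]:
    """Return (cdr1, cdr2, cdr2_5) germline strings for a V gene."""
    rows = vcdr_table.loc[vcdr_table["v_gene"] == v_gene]
    if rows.empty:
        raise KeyError(f"V gene {v_gene!r} not found in the CDR lookup table")
    row = rows.iloc[0]
    return row["cdr1"], row["cdr2"], row["cdr2_5"]


@dataclass(frozen=True)
class TCRFeatures:
    v_gene: str
    cdr1: str
    cdr2: str
    cdr2_5: str
    cdr3_padded: str
    cdr3_length: int


@dataclass
class EncodedPair:
    """Numeric tensors for one HLA + one TCR."""

    hla_tensor: np.ndarray          # (pseudo_len, channels)
    cdr3_tensor: np.ndarray         # (27, channels)
    cdr_flat: np.ndarray            # concat of CDR1/2/2.5/CDR3 encodings, flat
    cdr3_length_onehot: np.ndarray  # (27,)
    label: int | None = None


@dataclass
class EncodedDataset:
    """Stacked encoded pairs, ready for model training.

    ``hla`` is (n, pseudo_len, channels), ``cdr3`` is (n, 27, channels),
    ``cdr_flat`` is (n, flat_dim), ``cdr3_len_onehot`` is (n, 27) and
    ``labels`` is (n,) in {0, 1} (all -1 when unlabeled).
    """

    hla: np.ndarray
    cdr3: np.ndarray
    cdr_flat: np.ndarray
    cdr3_len_onehot: np.ndarray
    labels: np.ndarray
    pairs: pd.DataFrame  # tcr_id, allele (row-aligned with the tensors)
    scheme: str

    def __len__(self) -> int:
        return self.hla.shape[0]

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            self.hla[idx], self.cdr3[idx], self.cdr_flat[idx],
            self.cdr3_len_onehot[idx], self.labels[idx],
            self.pairs.iloc[idx].reset_index(drop=True), self.scheme,
        )

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "tensors.npz", hla=self.hla, cdr3=self.cdr3,
                 cdr_flat=self.cdr_flat, cdr3_len_onehot=self.cdr3_len_onehot,
                 labels=self.labels)
        self.pairs.to_csv(outdir / "pairs.csv", index=False)
        pd.Series({"scheme": self.scheme}).to_json(outdir / "manifest.json")

    @classmethod
    def load(cls, outdir: str | Path) -> "EncodedDataset":
        outdir = Path(outdir)
        z = np.load(outdir / "tensors.npz")
        manifest = pd.read_json(outdir / "manifest.json", typ="series")
        pairs = pd.read_csv(outdir / "pairs.csv")
        return cls(z["hla"], z["cdr3"], z["cdr_flat"], z["cdr3_len_onehot"],
                   z["labels"], pairs, str(manifest["scheme"]))


def _cdr3_length_onehot(length: int) -> np.ndarray:
    vec = np.zeros(CDR3_MAX_LEN, dtype=np.float32)
    vec[length - 1] = 1.0
    return vec


def encode_pair(
    allele: str,
    cdr3: str,
    v_gene: str,
    pseudo_table: pd.DataFrame,
    vcdr_table: pd.DataFrame,
    scheme: str = "one_hot",
    label: int | None = None,
) -> EncodedPair:
    """Featurize a single TCR-HLA pair.

    The HLA tensor is a function of the pseudo sequence only; two alleles
    sharing a pseudo sequence encode identically.
    """
    rows = pseudo_table.loc[pseudo_table["allele"] == allele, "pseudo_seq"]
    if rows.empty:
        raise KeyError(f"allele {allele!r} not in the pseudo-sequence table")
    pseudo = rows.iloc[0]
    cdr1, cdr2, cdr2_5 = lookup_v_gene_cdrs(v_gene, vcdr_table)
    padded = pad_cdr3(cdr3)
    cdr3_tensor = encode_sequence(padded, scheme)
    cdr_flat = np.concatenate([
        encode_sequence(cdr1, scheme).ravel(),
        encode_sequence(cdr2, scheme).ravel(),
        encode_sequence(cdr2_5, scheme).ravel(),
        cdr3_tensor.ravel(),
    ])
    return EncodedPair(
        hla_tensor=encode_sequence(pseudo, scheme),
        cdr3_tensor=cdr3_tensor,
        cdr_flat=cdr_flat.astype(np.float32),
        cdr3_length_onehot=_cdr3_length_onehot(len(cdr3)),
        label=label,
    )


def encode_pairs(
    pairs: pd.DataFrame,
    pseudo_table: pd.DataFrame,
    vcdr_table: pd.DataFrame,
    scheme: str = "one_hot",
) -> EncodedDataset:
    """Featurize a table of pairs (columns: tcr_id, allele, cdr3_aa, v_gene,
    optionally label) into stacked tensors.

    Lookups are cached per allele and per TCR so cohort-scale tables encode
    in one pass.
    """
    required = {"tcr_id", "allele", "cdr3_aa", "v_gene"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table is missing column(s) {sorted(missing)}")

    pseudo_of = dict(zip(pseudo_table["allele"], pseudo_table["pseudo_seq"]))
    hla_cache: dict[str, np.ndarray] = {}
    tcr_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    vcdr_cache: dict[str, tuple[str, str, str]] = {}

    hla_rows, cdr3_rows, flat_rows, len_rows = [], [], [], []
    for cdr3, v_gene, allele in zip(pairs["cdr3_aa"], pairs["v_gene"],
                                    pairs["allele"]):
        if allele not in hla_cache:
            if allele not in pseudo_of:
                raise KeyError(f"allele {allele!r} not in the pseudo-sequence table")
            hla_cache[allele] = encode_sequence(pseudo_of[allele], scheme)
        key = (cdr3, v_gene)
        if key not in tcr_cache:
            if v_gene not in vcdr_cache:
                vcdr_cache[v_gene] = lookup_v_gene_cdrs(v_gene, vcdr_table)
            cdr1, cdr2, cdr2_5 = vcdr_cache[v_gene]
            cdr3_tensor = encode_sequence(pad_cdr3(cdr3), scheme)
            flat = np.concatenate([
                encode_sequence(cdr1, scheme).ravel(),
                encode_sequence(cdr2, scheme).ravel(),
                encode_sequence(cdr2_5, scheme).ravel(),
                cdr3_tensor.ravel(),
            ]).astype(np.float32)
            tcr_cache[key] = (cdr3_tensor, flat, _cdr3_length_onehot(len(cdr3)))
        cdr3_tensor, flat, len1h = tcr_cache[key]
        hla_rows.append(hla_cache[allele])
        cdr3_rows.append(cdr3_tensor)
        flat_rows.append(flat)
        len_rows.append(len1h)

    labels = (pairs["label"].to_numpy(dtype=np.int64)
              if "label" in pairs.columns
              else np.full(len(pairs), -1, dtype=np.int64))
    return EncodedDataset(
        hla=np.stack(hla_rows) if hla_rows else np.zeros((0, 0, 0), np.float32),
        cdr3=np.stack(cdr3_rows) if cdr3_rows else np.zeros((0, 0, 0), np.float32),
        cdr_flat=np.stack(flat_rows) if flat_rows else np.zeros((0, 0), np.float32),
        cdr3_len_onehot=np.stack(len_rows) if len_rows else np.zeros((0, CDR3_MAX_LEN), np.float32),
        labels=labels,
        pairs=pairs[["tcr_id", "allele"]].reset_index(drop=True),
        scheme=scheme,
    )
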