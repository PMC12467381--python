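"""Compound and protein featurisation.

Compounds are encoded as hashed circular-substructure (Morgan/ECFP-style)
binary fingerprints.  Proteins are encoded by splitting each sequence into
k-mer "words" in ``frames`` shifted reading frames (the ProtVec convention),
training skip-gram word vectors on that corpus, and summing the vectors of a
sequence's k-mers.  Both encoders produce the fixed-length vectors consumed
by the interaction model: slot 1 is always the target (protein), slot 2 the
compound.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "ProteinRecord",
    "KmerEmbeddingTable",
    "morgan_fingerprint",
    "train_kmer_embeddings",
    "protein_embed",
    "featurize_pair",
    "read_fasta",
    "read_compound_table",
]


@dataclasses.dataclass
class CompoundRecord:
    """A compound: identifier, SMILES string and (optionally) its fingerprint."""

    compound_id: str
    smiles: str
    fingerprint: np.ndarray | None = None


@dataclasses.dataclass
class ProteinRecord:
    """A protein: identifier, amino-acid sequence and (optionally) its embedding."""

    protein_id: str
    sequence: str
    embedding: np.ndarray | None = None


def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> np.ndarray:
    """Hashed circular-substructure binary fingerprint of a molecule.

    Deterministic and invariant to the SMILES atom ordering (the hash runs on
    the molecular graph, not the string).

    Parameters
    ----------
    smiles : SMILES string; must parse to a valid molecule.
    radius : maximum bond radius of the hashed atom environments (2 gives the
        common ECFP4-like fingerprint).
    n_bits : fingerprint width.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.float64)


# ---------------------------------------------------------------------------
# k-mer skip-gram embeddings
# ---------------------------------------------------------------------------


def kmer_sentences(sequence: str, k: int, frames: int) -> Iterator[list[str]]:
    """Split a sequence into non-overlapping k-mer words in shifted frames.

    Frame f starts at offset f and steps by k, so with frames = k every
    position of the sequence contributes to exactly one word of one frame.
    Non-standard residues (B, J, U, X, Z, *) are kept as literal symbols.
    """
    seq = sequence.upper()
    for f in range(frames):
        words = [seq[i : i + k] for i in range(f, len(seq) - k + 1, k)]
        if words:
            yield words


@dataclasses.dataclass
class KmerEmbeddingTable:
    """Learned skip-gram vectors for the k-mers of a training corpus."""

    k: int
    dimension: int
    vectors: dict[str, np.ndarray]
    window: int = 5
    epochs: int = 3
    seed: int = 0

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.vectors

    def get(self, kmer: str) -> np.ndarray:
        """Vector for ``kmer``; zero vector when the k-mer was never seen."""
        v = self.vectors.get(kmer)
        if v is None:
            return np.zeros(self.dimension)
        return v

    def save(self, path: str | Path) -> None:
        """Write in the plain-text word2vec format (``count dim`` header)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for word in sorted(self.vectors):
                floats = " ".join(repr(float(x)) for x in self.vectors[word])
                fh.write(f"{word} {floats}\n")

    @classmethod
    def load(cls, path: str | Path, k: int | None = None) -> "KmerEmbeddingTable":
        with open(path) as fh:
            header = fh.readline().split()
            count, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
                if vectors[parts[0]].shape != (dim,):
                    raise ValueError(f"bad vector width for {parts[0]!r} in {path}")
        if len(vectors) != count:
            raise ValueError(f"header promised {count} vectors, found {len(vectors)}")
        if k is None:
            k = len(next(iter(vectors))) if vectors else 3
        return cls(k=k, dimension=dim, vectors=vectors)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def train_kmer_embeddings(
    sequences: Sequence[str],
    k: int = 3,
    dimension: int = 100,
    window: int = 5,
    epochs: int = 3,
    seed: int = 0,
    frames: int | None = None,
    negative: int = 5,
    batch_size: int = 512,
    lr: float = 0.025,
) -> KmerEmbeddingTable:
    """Train skip-gram (negative-sampling) embeddings on k-mer sentences.

    Each sequence is split into ``frames`` shifted reading frames of
    non-overlapping k-mers; every (centre, context) pair within ``window``
    words is a positive training example, contrasted against ``negative``
    noise words drawn from the unigram^0.75 distribution.  Fully seeded and
    reproducible: the same corpus + seed yields an identical table.
    """
    if frames is None:
        frames = k
    sentences = [s for seq in sequences for s in kmer_sentences(seq, k, frames)]
    if not sentences:
        raise ValueError(f"no sequence of length >= k={k} in the corpus")

    counts: dict[str, int] = {}
    for sent in sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted(counts, key=lambda w: (-counts[w], w))
    index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    centers, contexts = [], []
    for sent in sentences:
        idx = [index[w] for w in sent]
        for i, c in enumerate(idx):
            lo, hi = max(0, i - window), min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(idx[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dimension)) - 0.5) / dimension
    W_out = np.zeros((V, dimension))

    noise = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    noise /= noise.sum()

    n_pairs = len(centers)
    total_steps = max(1, epochs * ((n_pairs + batch_size - 1) // batch_size))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(V, size=(len(sel), negative), p=noise)
            eta = lr * max(1e-4 / lr, 1.0 - step / total_steps)
            step += 1

            vc = W_in[c]  # (B, D)
            # positive context
            g_pos = _sigmoid(np.einsum("bd,bd->b", vc, W_out[o])) - 1.0
            # negative contexts
            g_neg = _sigmoid(np.einsum("bd,bnd->bn", vc, W_out[neg]))

            d_vc = g_pos[:, None] * W_out[o] + np.einsum("bn,bnd->bd", g_neg, W_out[neg])
            d_out_pos = g_pos[:, None] * vc
            d_out_neg = g_neg[..., None] * vc[:, None, :]

            np.add.at(W_in, c, -eta * d_vc)
            np.add.at(W_out, o, -eta * d_out_pos)
            np.add.at(W_out, neg.ravel(), -eta * d_out_neg.reshape(-1, dimension))

    vectors = {w: W_in[index[w]].copy() for w in vocab}
    return KmerEmbeddingTable(
        k=k, dimension=dimension, vectors=vectors, window=window, epochs=epochs, seed=seed
    )


def protein_embed(
    sequence: str,
    table: KmerEmbeddingTable,
    frames: int = 3,
    aggregate: str = "sum",
) -> np.ndarray:
    """Embed a protein as the sum (or mean) of its k-mer word vectors.

    All k-mers of all ``frames`` shifted reading frames contribute; k-mers
    absent from the table contribute the zero vector.  The result is linear
    in the k-mer count vector, so sequences with identical k-mer multisets
    embed identically.
    """
    if len(sequence) < table.k:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than k={table.k}"
        )
    total = np.zeros(table.dimension)
    n = 0
    for words in kmer_sentences(sequence, table.k, frames):
        for w in words:
            total += table.get(w)
            n += 1
    if aggregate == "mean":
        return total / max(n, 1)
    if aggregate != "sum":
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return total


def featurize_pair(
    compound: CompoundRecord, protein: ProteinRecord
) -> tuple[np.ndarray, np.ndarray]:
    """Return the (target, compound) embedding pair for the model.

    Slot 1 is always the protein (target) embedding, slot 2 the compound
    fingerprint.
    """
    if protein.embedding is None:
        raise ValueError(f"protein {protein.protein_id!r} has no embedding")
    if compound.fingerprint is None:
        raise ValueError(f"compound {compound.compound_id!r} has no fingerprint")
    return np.asarray(protein.embedding, float), np.asarray(compound.fingerprint, float)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA; the id is the first token of the header."""
    return [
        ProteinRecord(protein_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read compounds from a delimited table or a .smi file.

    ``.smi`` files hold ``SMILES[ <whitespace> id]`` per line; anything else is
    a delimited table with (at least) columns ``compound_id`` and ``smiles``.
    Lines starting with ``#`` are metadata and skipped.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    if path.suffix == ".smi":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                cid = parts[1] if len(parts) > 1 else f"compound_{i}"
                records.append(CompoundRecord(compound_id=cid, smiles=parts[0]))
        return records
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "compound_id" not in cols or "smiles" not in cols:
        raise ValueError(f"{path}: expected columns compound_id, smiles; got {list(df.columns)}")
    for _, row in df.iterrows():
        records.append(CompoundRecord(compound_id=str(row[cols["compound_id"]]),
                                      smiles=str(row[cols["smiles"]])))
    return records
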