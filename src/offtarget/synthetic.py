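"""Self-contained synthetic screening world with a planted interaction rule.

The generator emulates the statistical shape of the data the framework
consumes, at desk scale and with zero downloads:

* compounds are small guaranteed-valid SMILES from a grammar over C/N/O
  chains, branches and rings; "active" compounds carry a planted substructure
  fragment, "decoy" compounds carry the same atoms permuted so the fragment
  is absent (property-matched hard negatives, in the spirit of benchmark
  decoy sets);
* proteins are random 20-letter sequences; adverse-effect targets carry a
  planted sequence motif, other targets and the control proteome do not;
* a pair is a true interaction exactly when the compound has the fragment
  AND the target has the motif, so the label is learnable from the two
  modalities jointly;
* each adverse-effect target is annotated with a handful of vocabulary terms
  split over 1-3 organ groups, and each active compound's ground-truth
  adverse-effect list is the union of its true interactors' terms, with a
  configurable fraction corrupted into misspellings/synonym variants;
* a term dictionary (preferred terms + systematic variants) accompanies the
  world for the normalisation stage.

Everything is driven by one seed; regeneration under the same parameters is
identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import pandas as pd
from rdkit import Chem

from .evaluation import TermDictionary
from .featurization import CompoundRecord, ProteinRecord
from .knowledge import AnnotationSet, TargetAnnotation, write_annotation_table

__all__ = [
    "SyntheticWorld",
    "generate_world",
    "world_to_files",
    "world_from_files",
    "corrupt_term",
    "DEFAULT_WORLD_PARAMS",
    "AE_VOCABULARY",
    "ORGAN_GROUPS",
]

# Openly composed adverse-event vocabulary (generic clinical terms).
AE_VOCABULARY = [
    "nausea", "headache", "dizziness", "haemorrhage", "fatigue", "rash",
    "pruritus", "vomiting", "diarrhoea", "constipation", "anaemia",
    "thrombocytopenia", "epistaxis", "haematuria", "bruising", "dyspnoea",
    "cough", "palpitations", "tachycardia", "bradycardia", "hypotension",
    "hypertension", "oedema", "insomnia", "somnolence", "tremor",
    "paraesthesia", "confusion", "depression", "anxiety", "alopecia",
    "urticaria", "arthralgia", "myalgia", "back pain", "abdominal pain",
    "dyspepsia", "anorexia", "weight increased", "weight decreased",
    "fever", "chills", "sweating", "flushing", "dry mouth", "taste disorder",
    "blurred vision", "tinnitus", "vertigo", "syncope", "convulsion",
    "renal impairment", "hepatotoxicity", "jaundice", "photosensitivity",
    "gingival bleeding", "melaena", "menorrhagia", "haemoptysis", "petechiae",
]

ORGAN_GROUPS = ["Heart", "Lung", "Kidney", "Cerebral", "Gastrointestinal", "Skin", "Ubiquitous"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Default study conditions: 200 compounds, 100 targets, seed 7 (test preset
# latent width 64 lives in the run configuration, not here).
DEFAULT_WORLD_PARAMS = dict(
    n_compounds=200,
    n_targets=100,
    n_positive_per_target=6,
    motif_smiles_fragment="OCCN",
    motif_sequence="HKWWHE",
    ae_vocab_size=40,
    variant_rate=0.2,
    seed=7,
    n_controls=100,
    null_world=False,
)

_BRITISH_AMERICAN = [
    ("haem", "hem"), ("oedema", "edema"), ("noea", "nea"), ("aesthesia", "esthesia"),
]


def corrupt_term(term: str, rng: np.random.Generator) -> str:
    """Produce a realistic misspelling / variant of an adverse-event term.

    Operations: single-character deletion, adjacent swap, duplication,
    substitution, pluralisation, British/American spelling swap.  Always
    returns a string different from the input.
    """
    ops = ["delete", "swap", "duplicate", "substitute", "plural", "dialect"]
    for _ in range(20):
        op = ops[rng.integers(len(ops))]
        t = term
        if op == "delete" and len(t) > 3:
            i = int(rng.integers(len(t)))
            t = t[:i] + t[i + 1 :]
        elif op == "swap" and len(t) > 3:
            i = int(rng.integers(len(t) - 1))
            if t[i] != t[i + 1]:
                t = t[:i] + t[i + 1] + t[i] + t[i + 2 :]
        elif op == "duplicate":
            i = int(rng.integers(len(t)))
            t = t[:i] + t[i] + t[i:]
        elif op == "substitute":
            i = int(rng.integers(len(t)))
            c = "abcdefghijklmnopqrstuvwxyz"[rng.integers(26)]
            t = t[:i] + c + t[i + 1 :]
        elif op == "plural" and not t.endswith("s"):
            t = t + "s"
        elif op == "dialect":
            for brit, amer in _BRITISH_AMERICAN:
                if brit in t:
                    t = t.replace(brit, amer)
                    break
        if t != term:
            return t
    return term + "x"


# ---------------------------------------------------------------------------
# SMILES grammar
# ---------------------------------------------------------------------------


def _random_scaffold(rng: np.random.Generator) -> str:
    """A random valid chain/branch/ring SMILES over C, N, O, ending in C."""
    n = int(rng.integers(4, 10))
    atoms = [str(rng.choice(["C", "C", "C", "N", "O"])) for _ in range(n - 1)] + ["C"]
    smiles = "".join(atoms)
    if rng.random() < 0.4:
        # branch off an interior carbon
        c_pos = [i for i, a in enumerate(atoms[:-1]) if a == "C"]
        if c_pos:
            i = int(rng.choice(c_pos))
            branch = "(" + "".join(str(rng.choice(["C", "O", "N"])) for _ in range(int(rng.integers(1, 3)))) + ")"
            smiles = "".join(atoms[: i + 1]) + branch + "".join(atoms[i + 1 :])
    if rng.random() < 0.3:
        smiles = "C1CCCC1" + smiles  # cyclopentane head group
    return smiles


def _permute_fragment(fragment: str, rng: np.random.Generator) -> str:
    """Shuffle a plain-chain fragment's atoms into a different arrangement."""
    atoms = list(fragment)
    if not all(a in "CNO" for a in atoms):
        raise ValueError(
            f"decoy construction needs a plain C/N/O chain fragment, got {fragment!r}"
        )
    for _ in range(50):
        perm = [atoms[i] for i in rng.permutation(len(atoms))]
        if perm != atoms:
            return "".join(perm)
    return "".join(reversed(atoms))


def _generate_compounds(
    n: int, fragment: str, rng: np.random.Generator
) -> tuple[list[CompoundRecord], dict[str, str]]:
    query = Chem.MolFromSmiles(fragment)
    if query is None:
        raise ValueError(f"motif fragment {fragment!r} is not chemically embeddable")
    n_active = n // 2
    records: list[CompoundRecord] = []
    roles: dict[str, str] = {}
    width = len(str(n))
    for i in range(n):
        active = i < n_active
        for _ in range(100):
            scaffold = _random_scaffold(rng)
            if active:
                smi = scaffold + fragment
            else:
                smi = scaffold + _permute_fragment(fragment, rng)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            has = mol.HasSubstructMatch(query)
            if has == active:
                break
        else:
            raise RuntimeError(f"could not embed compound {i} with rule={active}")
        cid = f"D{i:0{width}d}"
        records.append(CompoundRecord(compound_id=cid, smiles=smi))
        roles[cid] = "active" if active else "decoy"
    return records, roles


def _random_sequence(rng: np.random.Generator, lo: int = 60, hi: int = 100) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _generate_proteins(
    n_targets: int, n_controls: int, motif: str, rng: np.random.Generator
) -> tuple[list[ProteinRecord], list[ProteinRecord], list[str]]:
    n_motif = n_targets // 2
    targets: list[ProteinRecord] = []
    motif_ids: list[str] = []
    width = len(str(max(n_targets, n_controls)))
    for i in range(n_targets):
        with_motif = i < n_motif
        for _ in range(100):
            seq = _random_sequence(rng)
            if with_motif:
                pos = int(rng.integers(0, len(seq) - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif) :]
                break
            if motif not in seq:
                break
        pid = f"T{i:0{width}d}"
        targets.append(ProteinRecord(protein_id=pid, sequence=seq))
        if with_motif:
            motif_ids.append(pid)
    controls: list[ProteinRecord] = []
    for i in range(n_controls):
        for _ in range(100):
            seq = _random_sequence(rng)
            if motif not in seq:
                break
        controls.append(ProteinRecord(protein_id=f"C{i:0{width}d}", sequence=seq))
    return targets, controls, motif_ids


@dataclasses.dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, generated from one seed."""

    params: dict
    compounds: list[CompoundRecord]
    compound_roles: dict[str, str]
    targets: list[ProteinRecord]
    controls: list[ProteinRecord]
    pairs: pd.DataFrame
    annotations: AnnotationSet
    ground_truth: dict[str, list[str]]
    dictionary: TermDictionary

    @property
    def active_ids(self) -> list[str]:
        return [c for c, r in self.compound_roles.items() if r == "active"]

    @property
    def decoy_ids(self) -> list[str]:
        return [c for c, r in self.compound_roles.items() if r == "decoy"]

    @property
    def ae_target_ids(self) -> list[str]:
        return [r.target_id for r in self.annotations.records]

    @property
    def organ_map(self) -> dict[str, list[str]]:
        return {
            r.target_id: sorted(r.organ_terms) for r in self.annotations.records
        }

    @property
    def all_proteins(self) -> list[ProteinRecord]:
        return self.targets + self.controls


def generate_world(
    n_compounds: int = 200,
    n_targets: int = 100,
    n_positive_per_target: int = 6,
    motif_smiles_fragment: str = "OCCN",
    motif_sequence: str = "HKWWHE",
    ae_vocab_size: int = 40,
    variant_rate: float = 0.2,
    seed: int = 7,
    n_controls: int = 100,
    null_world: bool = False,
) -> SyntheticWorld:
    """Generate the full synthetic screening world.

    ``null_world=True`` keeps the same entities but randomly shuffles the
    pair labels, severing the planted rule — the leakage control.
    """
    if min(n_compounds, n_targets, n_positive_per_target, n_controls) <= 0:
        raise ValueError("all sizes must be positive")
    if not 0.0 <= variant_rate <= 1.0:
        raise ValueError("variant_rate must lie in [0, 1]")
    if ae_vocab_size > len(AE_VOCABULARY):
        raise ValueError(f"ae_vocab_size capped at {len(AE_VOCABULARY)}")
    params = dict(
        n_compounds=n_compounds, n_targets=n_targets,
        n_positive_per_target=n_positive_per_target,
        motif_smiles_fragment=motif_smiles_fragment,
        motif_sequence=motif_sequence, ae_vocab_size=ae_vocab_size,
        variant_rate=variant_rate, seed=seed, n_controls=n_controls,
        null_world=null_world,
    )
    rng = np.random.default_rng(seed)
    compounds, roles = _generate_compounds(n_compounds, motif_smiles_fragment, rng)
    targets, controls, motif_target_ids = _generate_proteins(
        n_targets, n_controls, motif_sequence, rng
    )
    active = [c.compound_id for c in compounds if roles[c.compound_id] == "active"]
    decoy = [c.compound_id for c in compounds if roles[c.compound_id] == "decoy"]
    nonmotif_ids = [t.protein_id for t in targets if t.protein_id not in motif_target_ids]

    P = n_positive_per_target
    rows: list[tuple[str, str, int]] = []
    for tid in motif_target_ids:
        pos = rng.choice(len(active), size=min(P, len(active)), replace=False)
        for i in pos:
            rows.append((active[i], tid, 1))
        neg = rng.choice(len(decoy), size=min(P // 2, len(decoy)), replace=False)
        for i in neg:
            rows.append((decoy[i], tid, 0))
    for tid in nonmotif_ids:
        neg = rng.choice(len(active), size=min(P - P // 2, len(active)), replace=False)
        for i in neg:
            rows.append((active[i], tid, 0))
    pairs = pd.DataFrame(rows, columns=["compound_id", "target_id", "label"])
    pairs = pairs.drop_duplicates(subset=["compound_id", "target_id"]).reset_index(drop=True)
    if null_world:
        labels = pairs["label"].to_numpy().copy()
        rng.shuffle(labels)
        pairs["label"] = labels

    # annotations for the motif (adverse-effect) targets
    vocab = AE_VOCABULARY[:ae_vocab_size]
    target_by_id = {t.protein_id: t for t in targets}
    records: list[TargetAnnotation] = []
    for j, tid in enumerate(motif_target_ids):
        n_terms = int(rng.integers(2, 9))
        terms = [vocab[i] for i in rng.choice(len(vocab), size=min(n_terms, len(vocab)), replace=False)]
        n_organs = int(rng.integers(1, 4))
        organs = [ORGAN_GROUPS[i] for i in rng.choice(len(ORGAN_GROUPS), size=n_organs, replace=False)]
        organ_terms: dict[str, list[str]] = {o: [] for o in organs}
        for i, term in enumerate(terms):
            organ_terms[organs[i % len(organs)]].append(term)
        organ_terms = {o: ts for o, ts in organ_terms.items() if ts}
        records.append(
            TargetAnnotation(
                target_id=tid,
                accession=f"P{j:05d}",
                ae_terms=terms,
                organ_terms=organ_terms,
                sequence_ref=tid,
                source_study={"synthetic"},
            )
        )
    annotations = AnnotationSet(records=records, provenance={"generator": params})

    # per-compound ground truth with injected variants
    terms_by_tid = {r.target_id: r.ae_terms for r in records}
    truth: dict[str, list[str]] = {}
    positives = pairs[pairs["label"] == 1]
    for cid, grp in positives.groupby("compound_id", sort=True):
        pool = sorted({t for tid in grp["target_id"] if tid in terms_by_tid for t in terms_by_tid[tid]})
        corrupted = []
        for term in pool:
            if rng.random() < variant_rate:
                corrupted.append(corrupt_term(term, rng))
            else:
                corrupted.append(term)
        truth[str(cid)] = corrupted

    synonyms: dict[str, str] = {}
    for term in vocab:
        for brit, amer in _BRITISH_AMERICAN:
            if brit in term:
                synonyms[term.replace(brit, amer)] = term
        if not term.endswith("s"):
            synonyms[term + "s"] = term
    dictionary = TermDictionary(preferred_terms=list(vocab), synonyms=synonyms)

    world = SyntheticWorld(
        params=params, compounds=compounds, compound_roles=roles,
        targets=targets, controls=controls, pairs=pairs,
        annotations=annotations, ground_truth=truth, dictionary=dictionary,
    )
    _check_planted_rule(world, motif_smiles_fragment, motif_sequence)
    return world


def _check_planted_rule(world: SyntheticWorld, fragment: str, motif: str) -> None:
    if world.params.get("null_world"):
        return
    query = Chem.MolFromSmiles(fragment)
    smiles = {c.compound_id: c.smiles for c in world.compounds}
    seqs = {t.protein_id: t.sequence for t in world.targets}
    for row in world.pairs.itertuples(index=False):
        mol = Chem.MolFromSmiles(smiles[row.compound_id])
        has_frag = mol.HasSubstructMatch(query)
        has_motif = motif in seqs[row.target_id]
        expected = int(has_frag and has_motif)
        if expected != row.label:
            raise AssertionError(
                f"planted rule violated for pair {row.compound_id}/{row.target_id}"
            )


# ---------------------------------------------------------------------------
# file round trip
# ---------------------------------------------------------------------------


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world in the exact formats the other modules read."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": d / "proteins.fasta",
        "compounds": d / "compounds.csv",
        "pairs": d / "pairs.csv",
        "annotations": d / "annotations.csv",
        "dictionary": d / "dictionary.csv",
        "ground_truth": d / "ground_truth.csv",
        "params": d / "params.json",
    }
    with open(paths["fasta"], "w") as fh:
        for rec in world.targets + world.controls:
            fh.write(f">{rec.protein_id}\n{rec.sequence}\n")
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in world.compounds],
            "smiles": [c.smiles for c in world.compounds],
            "role": [world.compound_roles[c.compound_id] for c in world.compounds],
        }
    ).to_csv(paths["compounds"], index=False)
    world.pairs.to_csv(paths["pairs"], index=False)
    write_annotation_table(world.annotations, paths["annotations"])
    rows = [{"preferred_term": t, "synonym": ""} for t in world.dictionary.preferred_terms]
    rows += [
        {"preferred_term": pref, "synonym": var}
        for var, pref in sorted(world.dictionary.synonyms.items())
    ]
    pd.DataFrame(rows).to_csv(paths["dictionary"], index=False)
    truth_rows = [
        {"compound_id": cid, "ae_term": term}
        for cid in sorted(world.ground_truth)
        for term in world.ground_truth[cid]
    ]
    pd.DataFrame(truth_rows, columns=["compound_id", "ae_term"]).to_csv(
        paths["ground_truth"], index=False
    )
    paths["params"].write_text(json.dumps(world.params, indent=2, sort_keys=True))
    return paths


def world_from_files(directory: str | Path) -> SyntheticWorld:
    """Regenerate the world from its stored generation parameters.

    Generation is deterministic, so rebuilding from ``params.json`` restores
    every field bit-for-bit; the flat files exist for the individual module
    readers and for interoperability.
    """
    params = json.loads((Path(directory) / "params.json").read_text())
    return generate_world(**params)
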