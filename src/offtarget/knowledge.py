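"""Target -> adverse-effect -> organ annotation knowledge base.

Holds the combined annotation resource linking protein targets (UniProt-style
accessions) to free-text adverse-effect terms grouped by organ system.
Supports merging of annotation sets with duplicate-target pooling,
declarative curation patches, organ-source ranking by per-organ term counts,
and hierarchical clustering of targets by the Levenshtein distance between
their canonicalised adverse-effect profiles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "TargetAnnotation",
    "AnnotationSet",
    "merge_annotation_sets",
    "apply_patch",
    "rank_organ_sources",
    "levenshtein",
    "cluster_targets_by_ae",
    "linkage_to_newick",
    "read_annotation_table",
    "write_annotation_table",
]


def _norm_term(term: str) -> str:
    return " ".join(term.strip().lower().split())


@dataclasses.dataclass
class TargetAnnotation:
    """One protein target with its adverse-effect terms and organ groups."""

    target_id: str
    accession: str
    ae_terms: list[str]
    organ_terms: dict[str, list[str]]
    sequence_ref: str | None = None
    source_study: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self):
        if not self.ae_terms:
            raise ValueError(f"target {self.target_id!r} has no adverse-effect terms")
        known = {_norm_term(t) for t in self.ae_terms}
        for organ, terms in self.organ_terms.items():
            extra = {_norm_term(t) for t in terms} - known
            if extra:
                raise ValueError(
                    f"organ group {organ!r} of {self.target_id!r} lists terms "
                    f"not in ae_terms: {sorted(extra)}"
                )

    def ae_profile(self) -> str:
        """Canonical profile string: terms lower-cased, sorted, ';'-joined."""
        return ";".join(sorted({_norm_term(t) for t in self.ae_terms}))


@dataclasses.dataclass
class AnnotationSet:
    """A collection of target annotations with unique accessions."""

    records: list[TargetAnnotation]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        accs = [r.accession for r in self.records]
        if len(accs) != len(set(accs)):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions in annotation set: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def by_accession(self) -> dict[str, TargetAnnotation]:
        return {r.accession: r for r in self.records}


def _union_terms(a: Iterable[str], b: Iterable[str]) -> list[str]:
    # case-insensitive, whitespace-normalised dedup; first-seen casing wins
    seen: dict[str, str] = {}
    for t in list(a) + list(b):
        seen.setdefault(_norm_term(t), t)
    return list(seen.values())


def merge_annotation_sets(a: AnnotationSet, b: AnnotationSet) -> AnnotationSet:
    """Merge two annotation sets, pooling records that share an accession.

    For a shared accession the adverse-effect terms, per-organ term lists and
    source-study labels are unioned (term comparison is case-insensitive).
    Conflicting sequence references under one accession indicate inconsistent
    inputs and raise.
    """
    merged: dict[str, TargetAnnotation] = {}
    for rec in a.records + b.records:
        if rec.accession not in merged:
            merged[rec.accession] = TargetAnnotation(
                target_id=rec.target_id,
                accession=rec.accession,
                ae_terms=list(rec.ae_terms),
                organ_terms={k: list(v) for k, v in rec.organ_terms.items()},
                sequence_ref=rec.sequence_ref,
                source_study=set(rec.source_study),
            )
            continue
        cur = merged[rec.accession]
        if (
            cur.sequence_ref is not None
            and rec.sequence_ref is not None
            and cur.sequence_ref != rec.sequence_ref
        ):
            raise ValueError(
                f"accession {rec.accession!r} maps to conflicting sequences "
                f"({cur.sequence_ref!r} vs {rec.sequence_ref!r})"
            )
        cur.ae_terms = _union_terms(cur.ae_terms, rec.ae_terms)
        for organ, terms in rec.organ_terms.items():
            cur.organ_terms[organ] = _union_terms(cur.organ_terms.get(organ, []), terms)
        cur.source_study |= set(rec.source_study)
        if cur.sequence_ref is None:
            cur.sequence_ref = rec.sequence_ref
    prov = {"merged_from": [a.provenance, b.provenance]}
    return AnnotationSet(records=list(merged.values()), provenance=prov)


def apply_patch(annotations: AnnotationSet, patch: Sequence[dict]) -> AnnotationSet:
    """Apply declarative curation edits after merging.

    Each patch entry is a dict with ``op`` in {"add_term", "remove_term"},
    an ``accession``, an ``organ_group`` and (for adds) a ``term`` — the
    mechanism for narrative curation notes such as adding an extra organ
    source to a specific receptor.
    """
    by_acc = {r.accession: r for r in annotations.records}
    for entry in patch:
        op, acc = entry["op"], entry["accession"]
        rec = by_acc.get(acc)
        if rec is None:
            raise KeyError(f"patch references unknown accession {acc!r}")
        if op == "add_term":
            organ, term = entry["organ_group"], entry["term"]
            rec.ae_terms = _union_terms(rec.ae_terms, [term])
            rec.organ_terms[organ] = _union_terms(rec.organ_terms.get(organ, []), [term])
        elif op == "remove_term":
            key = _norm_term(entry["term"])
            rec.ae_terms = [t for t in rec.ae_terms if _norm_term(t) != key]
            for organ in list(rec.organ_terms):
                rec.organ_terms[organ] = [
                    t for t in rec.organ_terms[organ] if _norm_term(t) != key
                ]
                if not rec.organ_terms[organ]:
                    del rec.organ_terms[organ]
            if not rec.ae_terms:
                raise ValueError(f"patch removed every term of {acc!r}")
        else:
            raise ValueError(f"unknown patch op {op!r}")
    return annotations


def rank_organ_sources(annotation: TargetAnnotation) -> str:
    """Organ groups ordered by descending adverse-effect count, '/'-joined.

    "Lung/Heart/Kidney" means more lung-related terms than heart, and more
    heart than kidney; ties break alphabetically.
    """
    if not annotation.organ_terms:
        raise ValueError(f"target {annotation.target_id!r} has no organ groups")
    ordered = sorted(
        annotation.organ_terms.items(), key=lambda kv: (-len(kv[1]), kv[0])
    )
    return "/".join(name for name, _ in ordered)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def cluster_targets_by_ae(
    annotations: AnnotationSet, k: int, linkage: str = "average"
) -> dict[str, int]:
    """Agglomerative clustering of targets by AE-profile edit distance.

    Pairwise Levenshtein distances between canonical AE-profile strings feed
    average-linkage (default) hierarchical clustering; the dendrogram is cut
    to exactly ``k`` clusters.  Targets with identical profiles merge at
    distance zero and always co-cluster.
    """
    n = len(annotations.records)
    if k > n:
        raise ValueError(f"cannot cut {n} targets into {k} clusters")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    profiles = [r.ae_profile() for r in annotations.records]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = levenshtein(profiles[i], profiles[j])
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return {
        rec.target_id: int(lab) for rec, lab in zip(annotations.records, labels)
    }


def cluster_linkage(annotations: AnnotationSet, linkage: str = "average") -> np.ndarray:
    """The raw linkage matrix for dendrogram export."""
    n = len(annotations.records)
    profiles = [r.ae_profile() for r in annotations.records]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = levenshtein(profiles[i], profiles[j])
    return hierarchy.linkage(squareform(D, checks=False), method=linkage)


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# I/O: long-format table and JSON round trip
# ---------------------------------------------------------------------------


def read_annotation_table(path: str | Path) -> AnnotationSet:
    """Long-format CSV/TSV: target_id, accession, organ_group, ae_term."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        records = [
            TargetAnnotation(
                target_id=r["target_id"],
                accession=r["accession"],
                ae_terms=r["ae_terms"],
                organ_terms=r["organ_terms"],
                sequence_ref=r.get("sequence_ref"),
                source_study=set(r.get("source_study", [])),
            )
            for r in payload["records"]
        ]
        return AnnotationSet(records=records, provenance=payload.get("provenance", {}))
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    need = {"target_id", "accession", "organ_group", "ae_term"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    records = []
    for (tid, acc), grp in df.groupby(["target_id", "accession"], sort=True):
        organ_terms: dict[str, list[str]] = {}
        for organ, og in grp.groupby("organ_group"):
            organ_terms[str(organ)] = _union_terms(og["ae_term"].astype(str), [])
        ae_terms = _union_terms(df.loc[grp.index, "ae_term"].astype(str), [])
        src = set()
        if "source_study" in grp.columns:
            src = set(grp["source_study"].dropna().astype(str))
        seq = None
        if "sequence_ref" in grp.columns and grp["sequence_ref"].notna().any():
            seq = str(grp["sequence_ref"].dropna().iloc[0])
        records.append(
            TargetAnnotation(
                target_id=str(tid), accession=str(acc), ae_terms=ae_terms,
                organ_terms=organ_terms, sequence_ref=seq, source_study=src,
            )
        )
    return AnnotationSet(records=records)


def write_annotation_table(annotations: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "records": [
                {
                    "target_id": r.target_id,
                    "accession": r.accession,
                    "ae_terms": r.ae_terms,
                    "organ_terms": r.organ_terms,
                    "sequence_ref": r.sequence_ref,
                    "source_study": sorted(r.source_study),
                }
                for r in annotations.records
            ],
            "provenance": annotations.provenance,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return
    rows = []
    for r in annotations.records:
        src = ";".join(sorted(r.source_study))
        for organ, terms in sorted(r.organ_terms.items()):
            for term in terms:
                rows.append(
                    dict(target_id=r.target_id, accession=r.accession,
                         organ_group=organ, ae_term=term,
                         sequence_ref=r.sequence_ref or "", source_study=src)
                )
    pd.DataFrame(rows).to_csv(path, index=False)
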