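"""Reading, writing and filtering of sequences and the two task datasets.

Sequences travel as FASTA; site and pair-effect tables as UTF-8 TSV with
a header row ('#' lines are comments). Dataset-construction filters
implemented here: negative balancing by residue-stratified sampling,
label-stratified train/test splitting, and removal of training pairs
that overlap a test set.
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import STANDARD_AA, STY, PPIEffectRecord, ProteinRecord, SiteRecord

_NONSTANDARD = set("BZJUO")
_STANDARD = set(STANDARD_AA)


def _normalize_sequence(raw: str) -> str:
    seq = raw.upper()
    return "".join(
        "X" if (c in _NONSTANDARD or c not in _STANDARD) else c for c in seq
    )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    The header token before the first whitespace becomes the id; sequences
    are uppercased and non-standard letters (B, Z, J, U, O, ...) map to 'X'.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(id=pid, sequence=_normalize_sequence(str(entry.seq))))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _protein_index(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    index: dict[str, ProteinRecord] = {}
    for p in proteins:
        if p.id in index:
            raise ValueError(f"duplicate protein id {p.id!r}")
        index[p.id] = p
    return index


def _read_table(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, encoding="utf-8")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    return df


def read_site_table(path: str | Path, proteins: Iterable[ProteinRecord]) -> list[SiteRecord]:
    """Read and validate a TSV of candidate sites against their proteins.

    Columns: protein_id, position (1-based), residue, label.
    """
    index = _protein_index(proteins)
    df = _read_table(path, ["protein_id", "position", "residue", "label"])
    records: list[SiteRecord] = []
    for row in df.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in index:
            raise ValueError(f"{path}: unknown protein id {pid!r}")
        rec = SiteRecord(
            protein_id=pid,
            position=int(row.position),
            residue=str(row.residue),
            label=int(row.label),
        )
        rec.validate_against(index[pid])
        records.append(rec)
    return records


def write_site_table(records: Iterable[SiteRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.protein_id, r.position, r.residue, r.label) for r in records],
        columns=["protein_id", "position", "residue", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_ppi_table(path: str | Path, proteins: Iterable[ProteinRecord]) -> list[PPIEffectRecord]:
    """Read and validate a TSV of pair-effect records.

    Columns: protein_a_id, protein_b_id, position (1-based, on A), label
    (1 = enhancement, 0 = inhibition).
    """
    index = _protein_index(proteins)
    df = _read_table(path, ["protein_a_id", "protein_b_id", "position", "label"])
    records: list[PPIEffectRecord] = []
    for row in df.itertuples(index=False):
        a, b = str(row.protein_a_id), str(row.protein_b_id)
        for pid in (a, b):
            if pid not in index:
                raise ValueError(f"{path}: unknown protein id {pid!r}")
        rec = PPIEffectRecord(
            protein_a_id=a, protein_b_id=b, position=int(row.position), label=int(row.label)
        )
        rec.validate_against(index[a])
        records.append(rec)
    return records


def write_ppi_table(records: Iterable[PPIEffectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.protein_a_id, r.protein_b_id, r.position, r.label) for r in records],
        columns=["protein_a_id", "protein_b_id", "position", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def _largest_remainder_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``:
    floors first, remainder by largest fractional part (ties by index)."""
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def read_keep_list(path: str | Path) -> set[str]:
    """Read a plain-text list of protein ids (one per line, '#' comments).

    Such lists typically come from an external redundancy-reduction run
    (sequence-identity clustering); records from proteins not on the
    list are dropped before negative balancing.
    """
    ids = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.split("#")[0].strip()
            if token:
                ids.add(token)
    if not ids:
        raise ValueError(f"keep list {path} contains no ids")
    return ids


def filter_sites_by_keep_list(
    records: Sequence[SiteRecord], keep: set[str]
) -> list[SiteRecord]:
    """Keep only site records whose protein is on the keep list."""
    return [r for r in records if r.protein_id in keep]


def balance_negatives(
    positives: Sequence[SiteRecord],
    negatives: Sequence[SiteRecord],
    seed: int,
) -> list[SiteRecord]:
    """All positives plus an equal number of negatives sampled without
    replacement, stratified so the S/T/Y proportions of the negative pool
    are preserved to the nearest integer (largest-remainder rule)."""
    n_pos = len(positives)
    if len(negatives) < n_pos:
        raise ValueError(
            f"cannot balance: {len(negatives)} negatives < {n_pos} positives"
        )
    by_res: dict[str, list[SiteRecord]] = collections.defaultdict(list)
    for rec in negatives:
        by_res[rec.residue].append(rec)
    residues = sorted(by_res)  # deterministic stratum order
    weights = np.array([len(by_res[r]) for r in residues], dtype=float)
    counts = _largest_remainder_allocation(weights, n_pos)
    # a stratum smaller than its quota spills over to the largest strata
    for i, r in enumerate(residues):
        excess = counts[i] - len(by_res[r])
        while excess > 0:
            j = int(np.argmax([len(by_res[x]) - counts[k] for k, x in enumerate(residues)]))
            counts[j] += 1
            counts[i] -= 1
            excess -= 1
    rng = np.random.default_rng(seed)
    chosen: list[SiteRecord] = []
    for i, r in enumerate(residues):
        pool = by_res[r]
        idx = rng.choice(len(pool), size=int(counts[i]), replace=False)
        chosen.extend(pool[j] for j in sorted(idx))
    return list(positives) + chosen


def split_train_test(
    records: Sequence, ratio: float, seed: int, label_of=lambda r: r.label
) -> tuple[list, list]:
    """Label-stratified random split.

    Per label stratum the train share is round(ratio * stratum size); the
    test set gets the remainder. Deterministic given the seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    strata: dict[int, list] = collections.defaultdict(list)
    for rec in records:
        strata[label_of(rec)].append(rec)
    rng = np.random.default_rng(seed)
    train: list = []
    test: list = []
    for label in sorted(strata):
        members = strata[label]
        if len(members) < 2:
            raise ValueError(
                f"stratum {label} has {len(members)} member(s); need >= 2 to split"
            )
        n_train = int(np.floor(ratio * len(members) + 0.5))
        n_train = min(max(n_train, 1), len(members) - 1)  # both halves non-empty
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in sorted(perm[:n_train]))
        test.extend(members[i] for i in sorted(perm[n_train:]))
    return train, test


def remove_overlaps(
    train: Sequence[PPIEffectRecord],
    tests: Sequence[Sequence[PPIEffectRecord]],
) -> list[PPIEffectRecord]:
    """Drop training pairs whose ordered key (A, B, position) appears in
    any test collection; survivor order is preserved. The key is
    directional: the phosphosite lives on protein A."""
    banned: set[tuple[str, str, int]] = set()
    for coll in tests:
        banned.update(rec.key for rec in coll)
    return [rec for rec in train if rec.key not in banned]
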