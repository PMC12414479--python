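"""Self-contained synthetic datasets with the statistical structure of the
two real tasks, plus a plantable sequence signal that the models can
provably learn.

Structure emulated:

* site task — candidate sites are all S/T/Y residues; classes are
  balanced (positives = negatives) as in the curated site dataset;
* pair task — ~70/30 enhancement/inhibition class imbalance at the pair
  level, with a label that depends on BOTH proteins so the partner
  stream of the effect models is genuinely informative.

The signal is a literal motif ("RR" by default) planted at fixed offsets
(-3, -2) upstream of a site: a site is functional iff the motif occupies
those offsets. A pair's label is enhancement iff (motif near the site on
A) XOR (a designated inhibitor trigram occurs in the first 20 residues of
B). Labels are optionally flipped with ``noise_rate``. Because the motif
rate in i.i.d. uniform sequences is ~1/400 per candidate, the generator
plants the motif (and the trigram) by overwriting residues; planting is
what makes the stated dataset sizes reachable at realistic lengths.

To keep the two tasks' planted signals from contaminating each other's
labels, :func:`simulate` uses disjoint protein pools: the first half of
the proteins carries the site task, the second half the pair task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import balance_negatives
from .types import STANDARD_AA, STY, PPIEffectRecord, ProteinRecord, SiteRecord

_AA = np.array(list(STANDARD_AA))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings. Defaults are the package's standard study
    conditions: 200 proteins of 50-100 residues, 400 balanced sites, 400
    pairs at a 70/30 enhancement/inhibition mix, noiseless labels."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (50, 100)
    n_sites: int = 400
    n_pairs: int = 400
    positive_fraction_sites: float = 0.5
    enhancement_fraction: float = 0.7
    signal_motif: str = "RR"
    motif_offsets: tuple[int, ...] = (-3, -2)
    inhibitor_trigram: str = "DED"
    inhibitor_fraction: float = 1.0 / 6.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 31:
            raise ValueError("minimum protein length must be >= 31 (one full window)")
        if not 0.0 < self.positive_fraction_sites < 1.0:
            raise ValueError("positive_fraction_sites must be in (0, 1)")
        if not 0.0 < self.enhancement_fraction < 1.0:
            raise ValueError("enhancement_fraction must be in (0, 1)")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if len(self.signal_motif) != len(self.motif_offsets):
            raise ValueError("signal_motif length must match motif_offsets")
        q = self.motif_probability
        if not 0.0 < q <= 1.0:
            raise ValueError(
                "enhancement_fraction unreachable with this inhibitor_fraction"
            )

    @property
    def motif_probability(self) -> float:
        """Per-pair probability of planting the motif so that
        P(enhancement) = P(motif XOR trigram) hits enhancement_fraction."""
        f, r = self.enhancement_fraction, self.inhibitor_fraction
        return (f - r) / (1.0 - 2.0 * r)


def motif_present(sequence: str, position: int, cfg: SynthConfig) -> bool:
    """Is the signal motif at its stated offsets around a 1-based position?"""
    for off, ch in zip(cfg.motif_offsets, cfg.signal_motif):
        idx = position + off - 1
        if idx < 0 or idx >= len(sequence) or sequence[idx] != ch:
            return False
    return True


def _plantable(position: int, L: int, cfg: SynthConfig) -> bool:
    return all(0 <= position + off - 1 < L for off in cfg.motif_offsets)


def _plant_motif(seq: list[str], position: int, cfg: SynthConfig) -> None:
    for off, ch in zip(cfg.motif_offsets, cfg.signal_motif):
        seq[position + off - 1] = ch


def _sty_positions(sequence: str) -> list[int]:
    return [i + 1 for i, c in enumerate(sequence) if c in STY]


def gen_proteins(cfg: SynthConfig, rng: np.random.Generator | None = None) -> list[ProteinRecord]:
    """i.i.d. uniform sequences over the 20 standard letters; each is
    resampled until it contains at least 3 phosphorylatable residues."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.length_range
    records = []
    for i in range(cfg.n_proteins):
        while True:
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(_AA, size=L))
            if sum(c in STY for c in seq) >= 3:
                break
        records.append(ProteinRecord(id=f"SYN{i:04d}", sequence=seq))
    return records


def _with_sequences(
    proteins: list[ProteinRecord], seqs: dict[str, list[str]]
) -> list[ProteinRecord]:
    return [ProteinRecord(id=p.id, sequence="".join(seqs[p.id])) for p in proteins]


def gen_site_dataset(
    cfg: SynthConfig,
    proteins: list[ProteinRecord],
    rng: np.random.Generator | None = None,
) -> tuple[list[SiteRecord], list[ProteinRecord]]:
    """Balanced site records over a protein pool.

    Plants the motif before randomly chosen candidate sites until the
    positive quota is reachable, labels every candidate by the motif rule
    on the final sequences, applies label noise, then balances classes.
    Returns the records and the (possibly mutated) proteins.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    seqs = {p.id: list(p.sequence) for p in proteins}
    n_pos = int(round(cfg.n_sites * cfg.positive_fraction_sites))
    n_neg = cfg.n_sites - n_pos

    def candidates() -> list[tuple[str, int]]:
        return [
            (pid, pos) for pid, seq in seqs.items() for pos in _sty_positions("".join(seq))
        ]

    def positive_count() -> int:
        return sum(
            motif_present("".join(seqs[pid]), pos, cfg) for pid, pos in candidates()
        )

    # plant one site at a time: a plant can overwrite a neighbouring
    # candidate (or a previous plant), so recheck the tally after each
    plantable = [c for c in candidates() if _plantable(c[1], len(seqs[c[0]]), cfg)]
    order = rng.permutation(len(plantable))
    cursor = 0
    n_found = positive_count()
    while n_found < n_pos:
        if cursor >= len(order):
            raise ValueError(
                f"only {n_found} motif-positive sites reachable but {n_pos} "
                "needed; increase n_proteins"
            )
        pid, pos = plantable[order[cursor]]
        cursor += 1
        if motif_present("".join(seqs[pid]), pos, cfg):
            continue
        _plant_motif(seqs[pid], pos, cfg)
        n_found = positive_count()

    # label every candidate from the final sequences, then add noise
    final = {pid: "".join(seq) for pid, seq in seqs.items()}
    positives: list[SiteRecord] = []
    negatives: list[SiteRecord] = []
    for pid, pos in candidates():
        label = int(motif_present(final[pid], pos, cfg))
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            label = 1 - label
        rec = SiteRecord(
            protein_id=pid, position=pos, residue=final[pid][pos - 1], label=label
        )
        (positives if label else negatives).append(rec)
    if len(positives) < n_pos:
        raise ValueError(
            f"{len(positives)} positive candidates after noise < {n_pos} needed; "
            "increase n_proteins"
        )
    if len(negatives) < n_neg:
        raise ValueError(
            f"{len(negatives)} negative candidates < {n_neg} needed; increase n_proteins"
        )
    pos_idx = rng.choice(len(positives), size=n_pos, replace=False)
    chosen_pos = [positives[i] for i in sorted(pos_idx)]
    if n_pos == n_neg:
        sites = balance_negatives(chosen_pos, negatives, seed=int(rng.integers(2**31)))
    else:
        neg_idx = rng.choice(len(negatives), size=n_neg, replace=False)
        sites = chosen_pos + [negatives[i] for i in sorted(neg_idx)]
    return sites, _with_sequences(proteins, seqs)


def gen_ppi_dataset(
    cfg: SynthConfig,
    proteins: list[ProteinRecord],
    rng: np.random.Generator | None = None,
) -> tuple[list[PPIEffectRecord], list[ProteinRecord]]:
    """Pair-effect records over a protein pool.

    Each record gets a distinct (protein A, site) slot with the site at
    position >= 30 (so the planted motif never collides with the partner
    trigram region); the motif is planted with the probability that makes
    the XOR label rule hit ``enhancement_fraction``, and the inhibitor
    trigram is planted into the first 20 residues of a random
    ``inhibitor_fraction`` of the pool. Labels are computed from the
    final sequences, so they are always rule-consistent.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to form pairs")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    seqs = {p.id: list(p.sequence) for p in proteins}
    ids = [p.id for p in proteins]

    # partner-side signal: plant the trigram in a fixed fraction of proteins
    n_trig = int(round(cfg.inhibitor_fraction * len(ids)))
    for j in rng.choice(len(ids), size=n_trig, replace=False):
        start = int(rng.integers(0, 20 - len(cfg.inhibitor_trigram) + 1))
        for k, ch in enumerate(cfg.inhibitor_trigram):
            seqs[ids[j]][start + k] = ch

    # candidate slots: the motif region must clear the 20-residue trigram
    # zone, and selected slots in one protein are kept >= 4 apart so one
    # slot's plant can never overwrite or fake another slot's signal
    min_pos = 21 - min(cfg.motif_offsets)
    min_gap = max(abs(o) for o in cfg.motif_offsets) + 1
    pool = [
        (pid, pos)
        for pid, seq in seqs.items()
        for pos in _sty_positions("".join(seq))
        if pos >= min_pos and _plantable(pos, len(seq), cfg)
    ]
    taken: dict[str, list[int]] = {}
    slots: list[tuple[str, int]] = []
    for j in rng.permutation(len(pool)):
        pid, pos = pool[j]
        if any(abs(pos - other) < min_gap for other in taken.get(pid, ())):
            continue
        taken.setdefault(pid, []).append(pos)
        slots.append((pid, pos))
        if len(slots) == cfg.n_pairs:
            break
    if len(slots) < cfg.n_pairs:
        raise ValueError(
            f"only {len(slots)} usable (protein, site) slots for {cfg.n_pairs} "
            "pairs; increase n_proteins"
        )
    q = cfg.motif_probability
    for pid, pos in slots:
        if rng.random() < q:
            _plant_motif(seqs[pid], pos, cfg)

    final = {pid: "".join(seq) for pid, seq in seqs.items()}
    records: list[PPIEffectRecord] = []
    for pid_a, pos in slots:
        others = [x for x in ids if x != pid_a]
        pid_b = others[int(rng.integers(len(others)))]
        m = motif_present(final[pid_a], pos, cfg)
        t = cfg.inhibitor_trigram in final[pid_b][:20]
        label = int(m != t)
        if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
            label = 1 - label
        records.append(
            PPIEffectRecord(protein_a_id=pid_a, protein_b_id=pid_b, position=pos, label=label)
        )
    return records, _with_sequences(proteins, seqs)


def a_only_bayes_accuracy(cfg: SynthConfig) -> float:
    """Best achievable pair-task accuracy for a predictor that sees only
    protein A (i.e. only the motif bit): 1 - inhibitor_fraction under the
    XOR rule, attenuated by label noise."""
    r, eps = cfg.inhibitor_fraction, cfg.noise_rate
    return (1.0 - eps) * (1.0 - r) + eps * r


@dataclass(frozen=True)
class SyntheticDataset:
    proteins: list[ProteinRecord]
    sites: list[SiteRecord]
    pairs: list[PPIEffectRecord]
    site_pool: list[str] = field(default_factory=list)
    pair_pool: list[str] = field(default_factory=list)


def simulate(cfg: SynthConfig) -> SyntheticDataset:
    """Full generation: disjoint protein pools for the two tasks.

    The first half of the proteins carries the site task, the second half
    the pair task, so the planted signals cannot contaminate each other's
    labels.
    """
    rng = np.random.default_rng(cfg.seed)
    proteins = gen_proteins(cfg, rng)
    half = len(proteins) // 2
    site_pool, pair_pool = proteins[:half], proteins[half:]
    sites, site_pool = gen_site_dataset(cfg, site_pool, rng)
    pairs, pair_pool = gen_ppi_dataset(cfg, pair_pool, rng)
    return SyntheticDataset(
        proteins=site_pool + pair_pool,
        sites=sites,
        pairs=pairs,
        site_pool=[p.id for p in site_pool],
        pair_pool=[p.id for p in pair_pool],
    )
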