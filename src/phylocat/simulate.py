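"""Synthetic orthogroup datasets with ground truth.

Emulates the statistical structure of orthology-inference output that
the filtering pipeline assumes, with the generating parameters
recorded so tests can measure parameter recovery:

* **occupancy heterogeneity** — each taxon has a capture probability
  drawn from a Beta distribution, shared across loci; a taxon's row is
  dropped from a locus (whole-row, matching orthogroup semantics) with
  one minus that probability;
* **rate heterogeneity** — each locus carries a lognormal rate
  multiplier scaling the expected substitutions on every branch,
  producing a conservation gradient across loci;
* **unreliable columns** — a fraction of columns is overwritten with
  i.i.d. uniform residues and assigned confidence scores from a "low"
  distribution, all other columns from a "high" one, mimicking the
  divergently-aligned regions a column-confidence scorer flags.

Sequences evolve along a random rooted binary tree under a 20-state
equal-exchangeability Markov model ("Jukes–Cantor-20").  Its per-branch
probability that a site is unchanged has the closed form

    p(same) = 1/20 + (19/20) * exp(-(20/19) * r * t)

with ``r`` the locus rate multiplier and ``t`` the branch length in
expected substitutions per site, which makes oracle checks possible
without external model files.  No indels are simulated; gaps in real
data enter the pipeline only through the alignments it is given.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .core import (
    AMINO20,
    CANONICAL_AA,
    OrthogroupAlignment,
    OrthogroupSet,
    ScoreTrack,
    TaxonUniverse,
    UsageError,
)

_AA_BYTES = np.frombuffer(CANONICAL_AA.encode("ascii"), dtype=np.uint8)


@dataclass
class SimParams:
    """Generating parameters of a synthetic orthogroup dataset.

    Defaults describe a modest transcriptome-scale study: 20 taxa,
    100 loci of 100–300 aligned residues, branch lengths averaging
    0.05 substitutions/site (pairwise tip depths around half a
    substitution per site), lognormal(0, 0.5) locus rate multipliers,
    Beta(8, 2) per-taxon capture (mean occupancy 80%), and 10%
    unreliable columns whose confidence scores (U[0,3]) are well
    separated from reliable ones (U[6,10]) on the 0–10 ZORRO scale.
    """

    n_taxa: int = 20
    n_loci: int = 100
    length_range: tuple[int, int] = (100, 300)
    branch_length_mean: float = 0.05
    rate_mu: float = 0.0
    rate_sigma: float = 0.5
    capture_alpha: float = 8.0
    capture_beta: float = 2.0
    noisy_fraction: float = 0.1
    low_score_range: tuple[float, float] = (0.0, 3.0)
    high_score_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise UsageError("n_taxa must be >= 3")
        if self.n_loci < 1:
            raise UsageError("n_loci must be >= 1")
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise UsageError("require 0 < Lmin <= Lmax")
        if self.rate_sigma < 0:
            raise UsageError("rate_sigma must be >= 0")
        if not 0 <= self.noisy_fraction <= 1:
            raise UsageError("noisy_fraction must be in [0, 1]")
        if self.branch_length_mean <= 0:
            raise UsageError("branch_length_mean must be > 0")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    rate_multipliers: dict[str, float]
    capture_probs: dict[str, float]
    noisy_columns: dict[str, tuple[int, ...]]
    tree_newick: str

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["noisy_columns"] = {k: list(v) for k, v in self.noisy_columns.items()}
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        data = json.loads(Path(path).read_text())
        data["noisy_columns"] = {
            k: tuple(v) for k, v in data["noisy_columns"].items()
        }
        return cls(**data)


def taxon_labels(n_taxa: int) -> list[str]:
    """Zero-padded labels whose lexicographic and numeric orders agree."""
    width = len(str(n_taxa))
    return [f"T{i:0{width}d}" for i in range(1, n_taxa + 1)]


def simulate_tree(
    n_taxa: int,
    branch_length_mean: float,
    seed: int | np.random.Generator,
) -> dendropy.Tree:
    """Random rooted binary tree by sequential random joins.

    Starting from the leaves, two random lineages are repeatedly
    joined under a new internal node until one root remains; every
    branch length is i.i.d. exponential with the given mean.  The
    construction is deterministic given the seed.
    """
    if n_taxa < 3:
        raise UsageError("n_taxa must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = taxon_labels(n_taxa)
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(int(j))
        left = nodes.pop(int(i))
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        left.edge.length = float(rng.exponential(branch_length_mean))
        right.edge.length = float(rng.exponential(branch_length_mean))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def _evolve_locus(
    tree: dendropy.Tree,
    length: int,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve one locus along *tree*; returns per-taxon residue codes."""
    leaf_seqs: dict[str, np.ndarray] = {}
    root_seq = rng.integers(0, 20, size=length, dtype=np.int64)
    seqs = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = seqs.pop(id(node))
        else:
            seq = seqs.pop(id(node)).copy()
            t = node.edge.length
            # JC-20: event rate (20/19)*r so realised substitutions = r*t
            p_event = 1.0 - np.exp(-(20.0 / 19.0) * rate * t)
            hits = rng.random(length) < p_event
            seq[hits] = rng.integers(0, 20, size=int(hits.sum()), dtype=np.int64)
        if node.taxon is not None:
            leaf_seqs[node.taxon.label] = seq
        for child in node.child_nodes():
            seqs[id(child)] = seq
    return leaf_seqs


def simulate_dataset(
    params: SimParams,
) -> tuple[OrthogroupSet, dict[str, ScoreTrack], SimTruth]:
    """Generate a full synthetic dataset with its ground truth.

    All randomness flows from ``params.seed`` through one generator in
    a fixed draw order (capture probabilities, tree, then per locus:
    length, rate, evolution, noisy columns, scores, taxon dropout), so
    identical parameters give byte-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    labels = taxon_labels(params.n_taxa)
    universe = TaxonUniverse(labels)

    if params.capture_beta == 0:
        # degenerate Beta limit: every taxon captured in every locus
        capture = np.ones(params.n_taxa)
    else:
        capture = rng.beta(params.capture_alpha, params.capture_beta, params.n_taxa)
    tree = simulate_tree(params.n_taxa, params.branch_length_mean, rng)

    lmin, lmax = params.length_range
    slo, shi = params.low_score_range
    hlo, hhi = params.high_score_range
    width = len(str(params.n_loci))

    loci: list[OrthogroupAlignment] = []
    tracks: dict[str, ScoreTrack] = {}
    rates: dict[str, float] = {}
    noisy: dict[str, tuple[int, ...]] = {}

    for g in range(1, params.n_loci + 1):
        og_id = f"OG{g:0{width}d}"
        length = int(rng.integers(lmin, lmax + 1))
        rate = float(rng.lognormal(params.rate_mu, params.rate_sigma))
        leaf = _evolve_locus(tree, length, rate, rng)

        noisy_mask = rng.random(length) < params.noisy_fraction
        noisy_idx = np.flatnonzero(noisy_mask)
        for col in noisy_idx:
            junk = rng.integers(0, 20, size=params.n_taxa, dtype=np.int64)
            for k, lab in enumerate(labels):
                leaf[lab][col] = junk[k]

        scores = rng.uniform(hlo, hhi, size=length)
        scores[noisy_idx] = rng.uniform(slo, shi, size=len(noisy_idx))

        present = rng.random(params.n_taxa) < capture
        rows = {
            lab: _AA_BYTES[leaf[lab]].tobytes().decode("ascii")
            for k, lab in enumerate(labels)
            if present[k]
        }
        loci.append(OrthogroupAlignment(og_id, rows, AMINO20, length))
        tracks[og_id] = ScoreTrack(og_id, tuple(float(s) for s in scores))
        rates[og_id] = rate
        noisy[og_id] = tuple(int(c) for c in noisy_idx)

    truth = SimTruth(
        rate_multipliers=rates,
        capture_probs={lab: float(c) for lab, c in zip(labels, capture)},
        noisy_columns=noisy,
        tree_newick=tree.as_string(schema="newick").strip(),
    )
    return OrthogroupSet(universe, loci), tracks, truth
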