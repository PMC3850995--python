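"""Synthetic structures and prediction lists with planted, known metric values.

The chain generator is a fixed-step self-avoidance-free random walk with a
harmonic pull toward the running centroid.  That is not a physical protein
model, but it produces what the metrics need: a compact fold whose contact
map has the banded short/medium-range structure plus genuine long-range
contacts.  The prediction generator plants exact numbers of true contacts,
near misses at a chosen Chebyshev offset, and clear false positives, so
every accuracy the metrics compute has a closed-form expected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .contact_map import (
    SEP_LONG,
    ContactMap,
    Residue,
    TargetStructure,
    build_contact_map,
    classify_separation,
)
from .rr_io import PredictionSet, ScoredPair

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Centroid-pull strength.  The default yields globules whose contact maps
#: are sparse (roughly 5-25% of long-range pairs in contact) yet always
#: contain long-range contacts for chains of 60+ residues.
DEFAULT_COMPACTNESS = 0.06
DEFAULT_STEP = 3.8


class PlantingError(ValueError):
    """Raised when the truth map cannot support the requested planting."""


@dataclass(frozen=True)
class ChainModel:
    """Parameters of the synthetic chain: length, Cα-Cα-like step (Å), compactness."""

    length: int
    step: float = DEFAULT_STEP
    compactness: float = DEFAULT_COMPACTNESS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 30:
            raise ValueError("length must be >= 30 for long-range contacts")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass(frozen=True)
class PlantSpec:
    """What to plant in a ranked prediction list of m pairs.

    round(p_exact * m) pairs are true contacts, round(p_near * m) pairs sit
    at Chebyshev distance exactly ``delta_near`` from some true contact, and
    the remainder are at Chebyshev distance > ``delta_near`` from every true
    contact.  All planted pairs belong to one separation class so that the
    class-filtered top-m selection is exactly the planted list.
    """

    m: int
    p_exact: float
    p_near: float = 0.0
    delta_near: int = 2
    sep_class: str = SEP_LONG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not (0 <= self.p_exact <= 1 and 0 <= self.p_near <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.p_exact + self.p_near > 1 + 1e-12:
            raise ValueError("p_exact + p_near must be <= 1")
        if self.p_near > 0 and self.delta_near < 1:
            raise ValueError("near misses require delta_near >= 1")

    def counts(self) -> tuple[int, int, int]:
        """(n_exact, n_near, n_false), exact integers by largest remainder."""
        n_exact = round(self.p_exact * self.m)
        n_near = round(self.p_near * self.m)
        while n_exact + n_near > self.m:  # rounding conflict
            rem_exact = self.p_exact * self.m - math.floor(self.p_exact * self.m)
            rem_near = self.p_near * self.m - math.floor(self.p_near * self.m)
            if rem_exact <= rem_near and n_exact > 0:
                n_exact -= 1
            else:
                n_near -= 1
        return n_exact, n_near, self.m - n_exact - n_near


def _walk(length: int, step: float, compactness: float, rng: np.random.Generator) -> np.ndarray:
    coords = np.zeros((length, 3))
    centroid = coords[0].copy()
    for t in range(1, length):
        g = rng.normal(size=3)
        g /= np.linalg.norm(g)
        direction = g + compactness * (centroid - coords[t - 1]) / step
        direction /= np.linalg.norm(direction)
        coords[t] = coords[t - 1] + step * direction
        centroid = coords[: t + 1].mean(axis=0)
    return coords


def generate_structure(model: ChainModel, max_retries: int = 50) -> TargetStructure:
    """Deterministic synthetic chain; consecutive residues exactly ``step`` apart.

    For chains of 60+ residues the walk is retried (with a deterministically
    perturbed seed) until the contact map contains at least one long-range
    contact, within a bounded retry budget.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng(model.seed + 1_000_003 * attempt)
        coords = _walk(model.length, model.step, model.compactness, rng)
        aa = rng.choice(list(AMINO_ACIDS), size=model.length)
        structure = TargetStructure(
            target_id=f"SYN-{model.seed}",
            length=model.length,
            residues=tuple(
                Residue(position=k + 1, aa=str(aa[k]), coords=coords[k])
                for k in range(model.length)
            ),
        )
        if model.length < 60:
            return structure
        cmap = build_contact_map(structure)
        if any(c.sep_class == SEP_LONG for c in cmap.contacts):
            return structure
    raise RuntimeError(
        f"no long-range contact after {max_retries} walks (seed {model.seed})"
    )


def _class_pairs(cmap: ContactMap, sep_class: str) -> np.ndarray:
    """All candidate (i, j) pairs of the class with both residues observed."""
    observed = np.array(sorted(cmap.observed_positions()), dtype=int)
    ii, jj = np.meshgrid(observed, observed, indexing="ij")
    mask = ii < jj
    pairs = np.column_stack([ii[mask], jj[mask]])
    sep = pairs[:, 1] - pairs[:, 0]
    if sep_class == "short":
        keep = (sep >= 6) & (sep < 12)
    elif sep_class == "medium":
        keep = (sep >= 12) & (sep < 24)
    elif sep_class == "long":
        keep = sep >= 24
    else:
        raise ValueError(f"cannot plant into class {sep_class!r}")
    return pairs[keep]


def _min_chebyshev(pairs: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Min over true contacts of max(|Δi|, |Δj|), for each candidate pair."""
    di = np.abs(pairs[:, None, 0] - truth[None, :, 0])
    dj = np.abs(pairs[:, None, 1] - truth[None, :, 1])
    return np.maximum(di, dj).min(axis=1)


def generate_predictions(truth: ContactMap, spec: PlantSpec) -> PredictionSet:
    """Ranked prediction list with exact planted hit counts.

    Scores decrease strictly in list order so the top-m selection is exactly
    the planted set; exact accuracy of that selection is n_exact/m and its
    neighbourhood accuracy at δ = delta_near is (n_exact + n_near)/m.
    """
    rng = np.random.default_rng(spec.seed)
    n_exact, n_near, n_false = spec.counts()

    truth_arr = np.array(sorted(truth.pairs), dtype=int).reshape(-1, 2)
    class_contacts = np.array(sorted(truth.pairs_of_class(spec.sep_class)), dtype=int).reshape(-1, 2)
    if len(class_contacts) < n_exact:
        raise PlantingError(
            f"need {n_exact} true {spec.sep_class}-range contacts, "
            f"truth has {len(class_contacts)}"
        )

    candidates = _class_pairs(truth, spec.sep_class)
    true_set = truth.pairs
    non_contact = candidates[
        ~np.array([(int(i), int(j)) in true_set for i, j in candidates])
    ]
    cheb = _min_chebyshev(non_contact, truth_arr) if len(truth_arr) else np.full(len(non_contact), np.inf)
    near_pool = non_contact[cheb == spec.delta_near]
    false_pool = non_contact[cheb > spec.delta_near]
    if len(near_pool) < n_near:
        raise PlantingError(
            f"need {n_near} near-miss pairs at Chebyshev {spec.delta_near}, "
            f"only {len(near_pool)} available"
        )
    if len(false_pool) < n_false:
        raise PlantingError(
            f"need {n_false} false pairs, only {len(false_pool)} available"
        )

    chosen = []
    idx = rng.choice(len(class_contacts), size=n_exact, replace=False)
    chosen.extend(map(tuple, class_contacts[idx]))
    idx = rng.choice(len(near_pool), size=n_near, replace=False)
    chosen.extend(map(tuple, near_pool[idx]))
    idx = rng.choice(len(false_pool), size=n_false, replace=False)
    chosen.extend(map(tuple, false_pool[idx]))

    order = rng.permutation(spec.m)
    scores = np.linspace(0.95, 0.05, spec.m)
    pairs = tuple(
        ScoredPair(
            i=int(chosen[k][0]),
            j=int(chosen[k][1]),
            dmin=0.0,
            dmax=truth.threshold,
            score=float(scores[rank]),
        )
        for rank, k in enumerate(order)
    )
    pairs = tuple(sorted(pairs, key=lambda p: -p.score))
    return PredictionSet(
        target_id=truth.target_id,
        predictor_id=f"planted-{spec.seed}",
        pairs=pairs,
        length=truth.length,
    )


@dataclass(frozen=True)
class SyntheticTarget:
    structure: TargetStructure
    contact_map: ContactMap
    predictions: PredictionSet
    planted_exact_accuracy: float
    planted_near_accuracy: float  # at delta = spec.delta_near
    delta_near: int


def generate_dataset(
    n_targets: int,
    model: ChainModel,
    spec: PlantSpec,
    seed: int,
    p_exact_per_target: Optional[Sequence[float]] = None,
) -> list[SyntheticTarget]:
    """Paired contact maps and prediction sets with recorded planted accuracies.

    Per-target seeds are derived deterministically from the master seed.
    ``p_exact_per_target`` overrides the template's exact-hit fraction per
    target, to produce heterogeneous planted accuracies.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if p_exact_per_target is not None and len(p_exact_per_target) != n_targets:
        raise ValueError("p_exact_per_target must have one entry per target")
    children = np.random.SeedSequence(seed).spawn(n_targets)
    out: list[SyntheticTarget] = []
    for k in range(n_targets):
        sub = int(children[k].generate_state(1)[0] % (2**31))
        tmodel = replace(model, seed=sub)
        tspec = replace(
            spec,
            seed=sub + 1,
            p_exact=(
                p_exact_per_target[k] if p_exact_per_target is not None else spec.p_exact
            ),
        )
        # a given walk may not hold enough contacts of the planted class;
        # retry with a deterministically perturbed seed within a budget
        for attempt in range(30):
            tm = replace(tmodel, seed=(tmodel.seed + 7_919 * attempt) % (2**31))
            structure = generate_structure(tm)
            structure = replace(structure, target_id=f"SYN{k:04d}")
            cmap = build_contact_map(structure)
            try:
                preds = generate_predictions(cmap, replace(tspec, seed=tm.seed + 1))
                break
            except PlantingError:
                continue
        else:
            raise PlantingError(
                f"target {k}: no feasible chain for the requested planting"
            )
        n_exact, n_near, _ = tspec.counts()
        out.append(
            SyntheticTarget(
                structure=structure,
                contact_map=cmap,
                predictions=preds,
                planted_exact_accuracy=n_exact / tspec.m,
                planted_near_accuracy=(n_exact + n_near) / tspec.m,
                delta_near=tspec.delta_near,
            )
        )
    return out


def to_fasta(structure: TargetStructure) -> str:
    seq = "".join(r.aa for r in structure.residues)
    return f">{structure.target_id}\n{seq}\n"


def to_pdb(structure: TargetStructure) -> str:
    """Schematic PDB rendering: CA (and, for non-glycine, CB) at the
    representative coordinates, sufficient to round-trip through
    :func:`contactbench.contact_map.read_structure`."""
    import gemmi

    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    st = gemmi.Structure()
    st.name = structure.target_id or "synthetic"
    mdl = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for r in structure.residues:
        if not r.observed:
            continue
        res = gemmi.Residue()
        res.name = three[r.aa]
        res.seqid = gemmi.SeqId(r.position, " ")
        for atom_name in ("CA",) if r.aa == "G" else ("CA", "CB"):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*r.coords)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    mdl.add_chain(chain)
    st.add_model(mdl)
    return st.make_pdb_string()
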