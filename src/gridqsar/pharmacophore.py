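"""Pharmacophore feature perception, common-hypothesis enumeration, scoring.

A pharmacophore hypothesis is a small set of typed feature sites (donor D,
acceptor A, hydrophobe H, negative/positive ionisable N/P, aromatic ring R)
with fixed 3D geometry, hypothesised to be the arrangement a ligand must
present to the receptor.  Hypotheses are found by enumerating k-site feature
combinations in each active molecule, binning their intersite distances, and
keeping combinations whose (type letters, binned distances) key recurs in
enough actives.  Hypotheses are then scored by how well the active set aligns
onto them (site / vector / volume scores), by the rarity of their geometry
(selectivity), and combined into a survival score:

    S = w_site*S_site + w_vec*S_vec + w_vol*S_vol + w_sel*S_sel
        + w_rev^m - w_E*dE + w_act*A

with the adjustable-weight terms for conformer strain (dE) and reference
activity (A) disabled by default.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule, kabsch

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("A", "D", "H", "N", "P", "R")

DEFAULT_MAX_SITES = 5
DEFAULT_DISTANCE_BIN = 1.0  # A
DEFAULT_SITE_TOLERANCE = 2.0  # A
HEAVY_ATOM_RADIUS = 1.7  # A, hard-sphere radius for volume overlap
VOLUME_SAMPLING_STEP = 0.4  # A

#: Editable SMARTS rule table for point features.  R (aromatic rings) and
#: H (hydrophobes) are perceived algorithmically below.
FEATURE_SMARTS: dict[str, list[str]] = {
    # H-bond donors: N/O/S bearing a hydrogen; site on the heavy atom,
    # direction along the mean H vector.
    "D": ["[#7;!H0]", "[#8;!H0]", "[#16;X2;!H0]"],
    # H-bond acceptors: carbonyl/oxide O, ether/hydroxyl O, pyridine-type n,
    # imine N, non-amide tertiary amine.  Quaternary and amide nitrogens are
    # excluded.
    "A": [
        "[OX1]",
        "[OX2;!$(O=*)]",
        "[nX2]",
        "[NX2;!$([N]~[O])]",
        "[NX3;H0;!$(N[C,S]=[O,S,N]);!$([N+]);!a]",
    ],
    # Negative ionisable: carboxylate / (thio)acid oxygens, phosphate, sulfate.
    "N": ["[CX3](=O)[OX1H0-,OX2H1]", "[SX4](=O)(=O)[OX1H0-,OX2H1]",
          "[PX4](=O)([OX1H0-,OX2H1])"],
    # Positive ionisable: protonated/protonatable aliphatic amines, amidine,
    # guanidine.
    "P": ["[NX3;H2,H1;!$(NC=[O,S,N]);!$(N[a]);!$(N[NX2]);!a;!$([N+0][#7])]",
          "[NX4+]", "[NX3][CX3]=[NX2]"],
}


@dataclass
class FeatureSite:
    """One perceived pharmacophore feature."""

    feature_type: str
    position: np.ndarray
    direction: np.ndarray | None = None
    source_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        self.position = np.asarray(self.position, dtype=float)
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float)
            n = float(np.linalg.norm(self.direction))
            if abs(n - 1.0) > 1e-6:
                if n < 1e-9:
                    raise ValueError("zero-length feature direction")
                self.direction = self.direction / n

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "FeatureSite":
        return FeatureSite(
            self.feature_type,
            R @ self.position + t,
            None if self.direction is None else R @ self.direction,
            self.source_atoms,
        )


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

def _with_explicit_h(mol: Molecule) -> Chem.Mol:
    rd = mol.rdmol
    if any(a.GetAtomicNum() == 1 for a in rd.GetAtoms()):
        return rd
    return Chem.AddHs(Chem.Mol(rd), addCoords=True)


def perceive_features(mol: Molecule) -> list[FeatureSite]:
    """Rule-based feature perception on a 3D molecule.

    Point features (D, A, N, P) come from the editable SMARTS table; aromatic
    rings (R) sit at ring centroids with the ring normal as direction;
    hydrophobes (H) are connected groups of two or more aliphatic carbons
    with no attached heteroatom, placed at the group centroid.
    """
    if mol.rdmol.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol.id!r} has no 3D coordinates")
    rd = _with_explicit_h(mol)
    coords = np.array(rd.GetConformer().GetPositions(), dtype=float)
    sites: list[FeatureSite] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()

    for ftype, patterns in FEATURE_SMARTS.items():
        for smarts in patterns:
            query = Chem.MolFromSmarts(smarts)
            for match in rd.GetSubstructMatches(query, uniquify=True):
                anchor = match[0]
                key = (ftype, (anchor,))
                if key in seen:
                    continue
                seen.add(key)
                direction = None
                if ftype == "D":
                    atom = rd.GetAtomWithIdx(anchor)
                    hvecs = [coords[nb.GetIdx()] - coords[anchor]
                             for nb in atom.GetNeighbors()
                             if nb.GetAtomicNum() == 1]
                    if hvecs:
                        v = np.mean(hvecs, axis=0)
                        n = np.linalg.norm(v)
                        if n > 1e-9:
                            direction = v / n
                sites.append(FeatureSite(ftype, coords[anchor], direction,
                                         (anchor,)))

    # aromatic rings
    ring_info = rd.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            pts = coords[list(ring)]
            centroid = pts.mean(axis=0)
            # ring normal: smallest principal axis of the ring atoms
            _, _, Vt = np.linalg.svd(pts - centroid)
            sites.append(FeatureSite("R", centroid, Vt[2], tuple(sorted(ring))))

    # hydrophobes: connected aliphatic carbons with only C/H neighbours
    hydro_atoms = set()
    for atom in rd.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if all(nb.GetAtomicNum() in (1, 6) for nb in atom.GetNeighbors()):
            hydro_atoms.add(atom.GetIdx())
    visited: set[int] = set()
    for start in sorted(hydro_atoms):
        if start in visited:
            continue
        group = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in rd.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in hydro_atoms and j not in group:
                    group.add(j)
                    stack.append(j)
        visited |= group
        if len(group) >= 2:
            idx = sorted(group)
            sites.append(FeatureSite("H", coords[idx].mean(axis=0),
                                     None, tuple(idx)))
    return sites


# ---------------------------------------------------------------------------
# Hypothesis enumeration
# ---------------------------------------------------------------------------

@dataclass
class PharmacophoreHypothesis:
    """A typed k-site geometry with its canonical key and match count."""

    id: str
    sites: list[FeatureSite]
    intersite_distances: np.ndarray
    key: tuple = ()
    match_count: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        letters = "".join(sorted(s.feature_type for s in self.sites))
        if self.id.split(".")[0] != letters:
            raise ValueError(
                f"hypothesis id {self.id!r} does not match site letters {letters}")
        self.intersite_distances = np.asarray(self.intersite_distances, float)
        k = len(self.sites)
        if len(self.intersite_distances) != k * (k - 1) // 2:
            raise ValueError("intersite distance vector has wrong length")

    @property
    def letters(self) -> str:
        return self.id.split(".")[0]

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])


def _pair_distances(pts: np.ndarray) -> np.ndarray:
    k = len(pts)
    return np.array([np.linalg.norm(pts[i] - pts[j])
                     for i in range(k) for j in range(i + 1, k)])


def _canonical_combination(
    combo: Sequence[FeatureSite], distance_bin: float
) -> tuple[tuple, list[FeatureSite]]:
    """Canonical (letters, binned-distance) key of a site combination.

    Sites are ordered by type letter; among permutations of same-letter
    sites the one with the lexicographically smallest binned pair-distance
    vector is chosen, making the key independent of input order.
    """
    by_letter: dict[str, list[FeatureSite]] = {}
    for s in combo:
        by_letter.setdefault(s.feature_type, []).append(s)
    letters = sorted(by_letter)
    group_perms = [list(itertools.permutations(by_letter[l])) for l in letters]
    best_key = None
    best_order: list[FeatureSite] | None = None
    for perm_combo in itertools.product(*group_perms):
        order = [s for group in perm_combo for s in group]
        pts = np.array([s.position for s in order])
        bins = tuple(int(round(d / distance_bin)) for d in _pair_distances(pts))
        if best_key is None or bins < best_key:
            best_key = bins
            best_order = order
    letter_str = "".join(s.feature_type for s in best_order)  # type: ignore[union-attr]
    return (letter_str, best_key), best_order  # type: ignore[return-value]


def enumerate_hypotheses(
    actives: Sequence[Molecule],
    max_sites: int = DEFAULT_MAX_SITES,
    distance_bin: float = DEFAULT_DISTANCE_BIN,
    min_match: int | None = None,
    features: Sequence[Sequence[FeatureSite]] | None = None,
) -> list[PharmacophoreHypothesis]:
    """Enumerate common k-site hypotheses across an active set.

    Every ``max_sites``-combination of each active's features is keyed by its
    sorted type letters and binned intersite distances; keys present in at
    least ``min_match`` actives (default ``ceil(0.9 * n_actives)``) become
    hypotheses.  Variants sharing a letter set are numbered ``.1, .2, ...``
    by decreasing match count, then lexicographic key.  Site coordinates are
    taken from the first active exhibiting the key.
    """
    if len(actives) < 2:
        raise ValueError("need at least 2 active molecules")
    if not 3 <= max_sites <= 7:
        raise ValueError("max_sites must be in 3..7")
    if min_match is None:
        min_match = math.ceil(0.9 * len(actives))
    if features is None:
        features = [perceive_features(m) for m in actives]

    keyed: dict[tuple, dict] = {}
    for mol, feats in zip(actives, features):
        if len(feats) < max_sites:
            continue
        for combo in itertools.combinations(feats, max_sites):
            key, order = _canonical_combination(combo, distance_bin)
            entry = keyed.setdefault(key, {"mols": set(), "first": None})
            if entry["first"] is None:
                entry["first"] = (mol.id, order)
            entry["mols"].add(mol.id)

    common = [(key, entry) for key, entry in keyed.items()
              if len(entry["mols"]) >= min_match]
    if not common:
        logger.warning("no feature-combination key is shared by >= %d actives",
                       min_match)
        return []

    # deterministic variant numbering per letter set
    common.sort(key=lambda kv: (kv[0][0], -len(kv[1]["mols"]), kv[0][1]))
    hypotheses: list[PharmacophoreHypothesis] = []
    counters: dict[str, int] = {}
    for key, entry in common:
        letters = key[0]
        counters[letters] = counters.get(letters, 0) + 1
        source_id, order = entry["first"]
        pts = np.array([s.position for s in order])
        hypotheses.append(PharmacophoreHypothesis(
            id=f"{letters}.{counters[letters]}",
            sites=list(order),
            intersite_distances=_pair_distances(pts),
            key=key,
            match_count=len(entry["mols"]),
            source_id=source_id,
        ))
    return hypotheses


# ---------------------------------------------------------------------------
# Site matching (shared with screening)
# ---------------------------------------------------------------------------

@dataclass
class SiteMatch:
    """Best type-respecting assignment of molecule features to hypothesis
    sites, with the rigid transform carrying the molecule into the
    hypothesis frame."""

    rmsd: float
    assignment: list[FeatureSite]
    rotation: np.ndarray
    translation: np.ndarray


def best_site_match(
    h: PharmacophoreHypothesis,
    features: Sequence[FeatureSite],
) -> SiteMatch | None:
    """Search type-respecting injective assignments of ``features`` onto the
    hypothesis sites, returning the assignment minimizing post-superposition
    site RMSD, or None when some required feature type is unavailable."""
    by_letter: dict[str, list[FeatureSite]] = {}
    for f in features:
        by_letter.setdefault(f.feature_type, []).append(f)
    # hypothesis site slots grouped by letter, remembering slot order
    slots: dict[str, list[int]] = {}
    for i, s in enumerate(h.sites):
        slots.setdefault(s.feature_type, []).append(i)
    for letter, idxs in slots.items():
        if len(by_letter.get(letter, [])) < len(idxs):
            return None
    target = h.positions()
    letters = sorted(slots)
    choices = [itertools.permutations(by_letter[l], len(slots[l]))
               for l in letters]
    best: SiteMatch | None = None
    for pick in itertools.product(*choices):
        assignment: list[FeatureSite | None] = [None] * len(h.sites)
        for letter, group in zip(letters, pick):
            for slot, feat in zip(slots[letter], group):
                assignment[slot] = feat
        pts = np.array([f.position for f in assignment])  # type: ignore[union-attr]
        R, t, rmsd = kabsch(pts, target)
        if best is None or rmsd < best.rmsd - 1e-12:
            best = SiteMatch(rmsd, list(assignment), R, t)  # type: ignore[arg-type]
    return best


# ---------------------------------------------------------------------------
# Volume overlap
# ---------------------------------------------------------------------------

def _heavy_coords(mol: Molecule) -> np.ndarray:
    rd = mol.rdmol
    idx = [a.GetIdx() for a in rd.GetAtoms() if a.GetAtomicNum() > 1]
    return np.array(rd.GetConformer().GetPositions(), dtype=float)[idx]


def volume_overlap(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    radius: float = HEAVY_ATOM_RADIUS,
    step: float = VOLUME_SAMPLING_STEP,
) -> float:
    """Shared / total (union) volume of two hard-sphere models, estimated on
    a fixed lattice of the given step.  Deterministic."""
    lo = np.minimum(coords_a.min(axis=0), coords_b.min(axis=0)) - radius
    hi = np.maximum(coords_a.max(axis=0), coords_b.max(axis=0)) + radius
    axes = [np.arange(lo[d], hi[d] + step, step) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def inside(coords: np.ndarray) -> np.ndarray:
        occ = np.zeros(len(pts), dtype=bool)
        r2 = radius * radius
        for c in coords:
            d2 = np.sum((pts - c) ** 2, axis=1)
            occ |= d2 <= r2
        return occ

    a = inside(coords_a)
    b = inside(coords_b)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b)) / union


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalWeights:
    """Weights of the survival score; strain and activity terms default off."""

    w_site: float = 1.0
    w_vec: float = 1.0
    w_vol: float = 1.0
    w_sel: float = 1.0
    w_rev: float = 0.0
    w_energy: float = 0.0
    w_act: float = 0.0
    m: int = 1

    def __post_init__(self) -> None:
        if any(w < 0 for w in (self.w_site, self.w_vec, self.w_vol,
                               self.w_sel, self.w_rev, self.w_energy,
                               self.w_act)):
            raise ValueError("weights must be >= 0")


@dataclass
class HypothesisScores:
    hypothesis_id: str
    site_score: float
    vector_score: float
    volume_score: float
    selectivity: float
    energy_term: float
    reference_activity: float
    matches: int
    survival: float
    survival_inactive: float | None = None


def survival_score(
    site_score: float, vector_score: float, volume_score: float,
    selectivity: float, w: SurvivalWeights = SurvivalWeights(),
    energy: float = 0.0, reference_activity: float = 0.0,
) -> float:
    """The weighted survival sum; exactly the linear combination of its terms
    (plus the configurable ``w_rev^m`` constant, disabled by default)."""
    return (w.w_site * site_score + w.w_vec * vector_score
            + w.w_vol * volume_score + w.w_sel * selectivity
            + w.w_rev ** w.m - w.w_energy * energy
            + w.w_act * reference_activity)


def _alignment_scores(
    h: PharmacophoreHypothesis,
    mols: Sequence[Molecule],
    tolerance: float,
    features: Sequence[Sequence[FeatureSite]] | None = None,
    reference_mol: Molecule | None = None,
) -> tuple[float, float, float, int]:
    """Mean site / vector / volume scores of a molecule set against the
    hypothesis, plus the number of molecules that could be assigned."""
    if features is None:
        features = [perceive_features(m) for m in mols]
    site_scores, vec_scores, vol_scores = [], [], []
    matched = 0
    for mol, feats in zip(mols, features):
        match = best_site_match(h, feats)
        if match is None:
            continue
        matched += 1
        site_scores.append(max(0.0, 1.0 - match.rmsd / tolerance))
        cosines = []
        for hyp_site, feat in zip(h.sites, match.assignment):
            if hyp_site.direction is not None and feat.direction is not None:
                moved = match.rotation @ feat.direction
                c = float(np.clip(np.dot(moved, hyp_site.direction), -1.0, 1.0))
                if hyp_site.feature_type == "R":
                    c = abs(c)  # ring normals have no preferred sign
                cosines.append(c)
        vec_scores.append(float(np.mean(cosines)) if cosines else 1.0)
        if reference_mol is not None:
            moved_coords = _heavy_coords(mol) @ match.rotation.T + match.translation
            vol_scores.append(volume_overlap(moved_coords,
                                             _heavy_coords(reference_mol)))
        else:
            vol_scores.append(1.0)
    if matched == 0:
        return 0.0, 0.0, 0.0, 0
    return (float(np.mean(site_scores)), float(np.mean(vec_scores)),
            float(np.mean(vol_scores)), matched)


def selectivity_score(
    h: PharmacophoreHypothesis,
    actives: Sequence[Molecule],
    max_sites: int | None = None,
    distance_bin: float = DEFAULT_DISTANCE_BIN,
    features: Sequence[Sequence[FeatureSite]] | None = None,
) -> float:
    """Rarity of the hypothesis geometry: ``-log10`` of the fraction of all
    k-site feature combinations in the set that share its canonical key
    (floored at 1e-6, so the score is capped at 6)."""
    k = max_sites or len(h.sites)
    if features is None:
        features = [perceive_features(m) for m in actives]
    total = 0
    hits = 0
    for feats in features:
        for combo in itertools.combinations(feats, k):
            total += 1
            key, _ = _canonical_combination(combo, distance_bin)
            if key == h.key:
                hits += 1
    if total == 0:
        return 0.0
    frac = max(hits / total, 1e-6)
    return -math.log10(frac)


def score_hypothesis(
    h: PharmacophoreHypothesis,
    actives: Sequence[Molecule],
    inactives: Sequence[Molecule] | None = None,
    weights: SurvivalWeights = SurvivalWeights(),
    tolerance: float = DEFAULT_SITE_TOLERANCE,
    distance_bin: float = DEFAULT_DISTANCE_BIN,
    energy: float = 0.0,
    reference_activity: float = 0.0,
    reference_mol: Molecule | None = None,
    active_features: Sequence[Sequence[FeatureSite]] | None = None,
) -> HypothesisScores:
    """Score a hypothesis against the active (and optional inactive) set."""
    if reference_mol is None:
        reference_mol = next((m for m in actives if m.id == h.source_id),
                             actives[0] if actives else None)
    site, vec, vol, matched = _alignment_scores(h, actives, tolerance,
                                                active_features, reference_mol)
    sel = selectivity_score(h, actives, distance_bin=distance_bin,
                            features=active_features)
    surv = survival_score(site, vec, vol, sel, weights, energy,
                          reference_activity)
    surv_inactive = None
    if inactives:
        isite, ivec, ivol, _ = _alignment_scores(h, inactives, tolerance,
                                                 None, reference_mol)
        inact = survival_score(isite, ivec, ivol, 0.0, weights, energy, 0.0)
        surv_inactive = surv - inact
    else:
        logger.info("no inactive set supplied; survival-inactive omitted")
    return HypothesisScores(
        hypothesis_id=h.id, site_score=site, vector_score=vec,
        volume_score=vol, selectivity=sel, energy_term=energy,
        reference_activity=reference_activity, matches=matched,
        survival=surv, survival_inactive=surv_inactive)


def rank_hypotheses(
    scored: Sequence[tuple[PharmacophoreHypothesis, HypothesisScores]],
) -> list[tuple[PharmacophoreHypothesis, HypothesisScores]]:
    """Rank by survival (desc), ties by selectivity (desc), then id."""
    if not scored:
        raise ValueError("nothing to rank")
    return sorted(scored, key=lambda hs: (-hs[1].survival,
                                          -hs[1].selectivity,
                                          hs[0].id))
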