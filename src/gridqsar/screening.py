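"""Library screening against a pharmacophore hypothesis with QSAR prediction.

Each library molecule is matched onto the hypothesis (best type-respecting
site assignment), carried into the training frame by the match transform,
its grid-field descriptors evaluated on the training grid, and its activity
predicted with the QSAR equation.  Externally computed scores (e.g. docking)
can be merged into the final report but are never computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import Molecule, assign_peoe_charges
from .fields import GridSpec, compute_descriptor_values, parse_descriptor_name
from .pharmacophore import (DEFAULT_SITE_TOLERANCE, PharmacophoreHypothesis,
                            best_site_match, perceive_features, volume_overlap,
                            _alignment_scores, _heavy_coords)
from .qsar import QSARModel

logger = logging.getLogger(__name__)

DEFAULT_FITNESS_WEIGHTS = (1.0, 1.0, 1.0)


@dataclass
class MatchResult:
    """Outcome of screening one library molecule."""

    compound_id: str
    matched: bool
    align_score: float = float("nan")  # site RMSD in Angstrom
    vector_score: float = float("nan")
    volume_score: float = float("nan")
    fitness: float = float("nan")
    predicted_activity: float | None = None
    external_score: float | None = None


def published_model() -> QSARModel:
    """The published four-descriptor grid-field QSAR equation for the
    thiosemicarbazone cathepsin-L series:

    ``pIC50 = 3.89857*E_86 + 3.12363*E_943 - 0.114297*E_463
              + 0.0152502*S_482 + 5.73211``

    Three electrostatic descriptors and one steric; E_463 contributes
    negatively.  Useful as a fixture for predicting activities of screened
    compounds on a matching grid.
    """
    return QSARModel(
        descriptor_names=["E_86", "E_943", "E_463", "S_482"],
        coefficients=[3.89857, 3.12363, -0.114297, 0.0152502],
        intercept=5.73211,
        n_components=4,
    )


def match_molecule(
    h: PharmacophoreHypothesis,
    mol: Molecule,
    tolerance: float = DEFAULT_SITE_TOLERANCE,
    weights: tuple[float, float, float] = DEFAULT_FITNESS_WEIGHTS,
    reference_mol: Molecule | None = None,
) -> MatchResult:
    """Match one molecule onto a hypothesis.

    fitness = w1*(1 - align/tolerance) + w2*vector + w3*volume.  A molecule
    lacking a required feature type, or whose best site RMSD exceeds the
    tolerance, returns ``matched=False`` rather than raising.
    """
    feats = perceive_features(mol)
    match = best_site_match(h, feats)
    if match is None or match.rmsd > tolerance:
        return MatchResult(mol.id, matched=False)
    cosines = []
    for hyp_site, feat in zip(h.sites, match.assignment):
        if hyp_site.direction is not None and feat.direction is not None:
            c = float(np.clip(np.dot(match.rotation @ feat.direction,
                                     hyp_site.direction), -1.0, 1.0))
            if hyp_site.feature_type == "R":
                c = abs(c)
            cosines.append(c)
    vector = float(np.mean(cosines)) if cosines else 1.0
    if reference_mol is not None:
        moved = _heavy_coords(mol) @ match.rotation.T + match.translation
        volume = volume_overlap(moved, _heavy_coords(reference_mol))
    else:
        volume = 1.0
    w1, w2, w3 = weights
    fitness = w1 * (1.0 - match.rmsd / tolerance) + w2 * vector + w3 * volume
    result = MatchResult(mol.id, True, match.rmsd, vector, volume, fitness)
    result._transform = (match.rotation, match.translation)  # type: ignore[attr-defined]
    return result


def screen_library(
    h: PharmacophoreHypothesis,
    library: Sequence[Molecule],
    model: QSARModel,
    grid: GridSpec,
    top_n: int | None = None,
    tolerance: float = DEFAULT_SITE_TOLERANCE,
    weights: tuple[float, float, float] = DEFAULT_FITNESS_WEIGHTS,
    reference_mol: Molecule | None = None,
) -> list[MatchResult]:
    """Screen a library: match, align into the training frame, compute the
    model's grid descriptors, predict activity, rank by fitness (ties by
    predicted activity descending, then id)."""
    for name in model.descriptor_names:
        grid.point(parse_descriptor_name(name)[1])  # raises if out of range
    results: list[MatchResult] = []
    for mol in library:
        res = match_molecule(h, mol, tolerance, weights, reference_mol)
        if res.matched:
            R, t = res._transform  # type: ignore[attr-defined]
            placed = mol.with_coords(mol.coords @ R.T + t)
            placed.partial_charges = None
            placed = assign_peoe_charges(placed)
            values = compute_descriptor_values(placed, grid,
                                               model.descriptor_names)
            res.predicted_activity = float(model.predict(values))
        results.append(res)
    matched = [r for r in results if r.matched]
    unmatched = [r for r in results if not r.matched]
    matched.sort(key=lambda r: (-r.fitness,
                                -(r.predicted_activity or -np.inf),
                                r.compound_id))
    ranked = matched + unmatched
    return ranked[:top_n] if top_n is not None else ranked


def merge_external_scores(
    results: Sequence[MatchResult],
    scores_csv: str | Path,
    rerank: bool = False,
) -> list[MatchResult]:
    """Attach externally computed scores (e.g. docking) from a CSV with
    ``compound_id`` and a score column; optionally re-rank ascending
    (docking convention: more negative is better)."""
    try:
        df = pd.read_csv(scores_csv)
    except pd.errors.EmptyDataError:
        return list(results)
    if df.empty and len(df.columns) == 0:
        return list(results)
    cols = {c.lower().strip(): c for c in df.columns}
    if "compound_id" not in cols:
        raise ValueError(f"{scores_csv}: missing 'compound_id' column")
    score_col = next((cols[c] for c in cols if c != "compound_id"), None)
    if score_col is None:
        raise ValueError(f"{scores_csv}: no score column")
    lookup = dict(zip(df[cols["compound_id"]].astype(str), df[score_col]))
    out = []
    for r in results:
        r = MatchResult(**{k: getattr(r, k) for k in
                           ("compound_id", "matched", "align_score",
                            "vector_score", "volume_score", "fitness",
                            "predicted_activity", "external_score")})
        if r.compound_id in lookup:
            r.external_score = float(lookup[r.compound_id])
        else:
            warnings.warn(f"no external score for {r.compound_id}")
        out.append(r)
    if rerank:
        out.sort(key=lambda r: (np.inf if r.external_score is None
                                else r.external_score))
    return out


def results_table(results: Sequence[MatchResult]) -> pd.DataFrame:
    """Hit report with the conventional screening-report columns."""
    return pd.DataFrame([{
        "compound_id": r.compound_id,
        "external_score": r.external_score,
        "align_score": r.align_score,
        "vector_score": r.vector_score,
        "volume_score": r.volume_score,
        "fitness": r.fitness,
        "predicted_activity": r.predicted_activity,
    } for r in results])
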