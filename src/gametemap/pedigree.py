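"""Parentage verification and likelihood-based parental genotype correction.

Offspring are matched to candidate (mother, father) pairs by the fraction
of trio-complete markers without a Mendelian violation.  Parental calls are
then corrected or imputed per marker by maximising the joint likelihood of
the pooled half-sib progeny under Mendelian transmission with a symmetric
genotype-error channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, Pedigree

# transmitted-alt-allele probability per parental dosage
_TRANSMIT = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])  # P(allele=0), P(allele=1)


def mendelian_consistent_table() -> np.ndarray:
    """bool[gm, gf, o]: can parents with dosages gm, gf produce dosage o?

    Missing codes are handled by callers; indices are the true dosages 0..2.
    """
    tab = np.zeros((3, 3, 3), dtype=bool)
    for gm in range(3):
        for gf in range(3):
            for am in ([0] if gm == 0 else [1] if gm == 2 else [0, 1]):
                for af in ([0] if gf == 0 else [1] if gf == 2 else [0, 1]):
                    tab[gm, gf, am + af] = True
    return tab


_CONSISTENT = mendelian_consistent_table()


def offspring_dosage_probs() -> np.ndarray:
    """P[gm, gf, o]: Mendelian offspring-dosage distribution."""
    p = np.zeros((3, 3, 3))
    for gm in range(3):
        for gf in range(3):
            for am in (0, 1):
                for af in (0, 1):
                    p[gm, gf, am + af] += _TRANSMIT[gm, am] * _TRANSMIT[gf, af]
    return p


def _observation_probs(eps: float) -> np.ndarray:
    """P[true, obs] under the symmetric error channel: the observed dosage
    equals the truth w.p. 1-eps, otherwise one of the other two w.p. eps/2."""
    q = np.full((3, 3), eps / 2.0)
    np.fill_diagonal(q, 1.0 - eps)
    return q


@dataclass
class ParentageResult:
    offspring: str
    mother: str | None
    father: str | None
    score: float
    n_markers: int
    resolved: bool
    reason: str = ""
    all_scores: pd.DataFrame | None = None


def assign_parentage(
    geno: GenotypeMatrix,
    offspring: str,
    candidate_mothers: list[str],
    candidate_fathers: list[str],
    min_score: float = 0.95,
    max_markers: int | None = None,
    seed: int = 0,
) -> ParentageResult:
    """Score every candidate pair by Mendelian concordance and return the
    best pair if its score clears ``min_score``.

    Ties are broken by the higher trio-complete marker count, then by
    lexicographic (mother, father) id.
    """
    if not candidate_mothers or not candidate_fathers:
        raise ValueError("need at least one candidate of each sex")
    o = geno.row(offspring)
    if max_markers is not None and geno.n_markers > max_markers:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(geno.n_markers, size=max_markers, replace=False))
        o = o[keep]
    else:
        keep = slice(None)
    if np.all(o < 0):
        return ParentageResult(offspring, None, None, np.nan, 0, False, "all markers missing")
    rows = []
    for mom in candidate_mothers:
        gm = geno.row(mom)[keep]
        for dad in candidate_fathers:
            gf = geno.row(dad)[keep]
            complete = (o >= 0) & (gm >= 0) & (gf >= 0)
            n = int(complete.sum())
            if n == 0:
                rows.append((mom, dad, np.nan, 0))
                continue
            ok = _CONSISTENT[gm[complete], gf[complete], o[complete]]
            rows.append((mom, dad, float(ok.mean()), n))
    scores = pd.DataFrame(rows, columns=["mother", "father", "score", "n_markers"])
    ranked = scores.sort_values(
        ["score", "n_markers", "mother", "father"],
        ascending=[False, False, True, True],
    )
    best = ranked.iloc[0]
    if np.isnan(best["score"]) or best["score"] < min_score:
        return ParentageResult(
            offspring, None, None, float(best["score"]), int(best["n_markers"]),
            False, "no pair reached min_score", scores,
        )
    return ParentageResult(
        offspring, str(best["mother"]), str(best["father"]), float(best["score"]),
        int(best["n_markers"]), True, "", scores,
    )


def verify_pedigree(
    geno: GenotypeMatrix,
    ped: Pedigree,
    min_score: float = 0.95,
    max_markers: int | None = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-assign every offspring against all candidate parents; report the
    best pair, its score, and whether it matches the recorded pedigree."""
    rows = []
    for r in ped.table.itertuples(index=False):
        res = assign_parentage(
            geno, r.offspring, ped.mothers, ped.fathers,
            min_score=min_score, max_markers=max_markers, seed=seed,
        )
        rows.append(
            (r.offspring, r.mother, r.father, res.mother, res.father, res.score,
             res.resolved, res.mother == r.mother and res.father == r.father)
        )
    return pd.DataFrame(
        rows,
        columns=["offspring", "mother", "father", "best_mother", "best_father",
                 "score", "resolved", "matches_pedigree"],
    )


def correct_parental_genotypes(
    geno: GenotypeMatrix,
    ped: Pedigree,
    focal_parent: str,
    epsilon: float = 0.01,
    min_family: int = 50,
    margin: float = float(np.log(10.0)),
    marginalize_other: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Correct/impute the focal parent's dosages from its pooled half-sib
    progeny.

    Per marker, the focal genotype g in {0,1,2} maximising
    prod_i P(o_i | g, g_other_i, eps) is adopted when it differs from the
    original call by a log-likelihood margin > ``margin``; markers with
    fewer than ``min_family`` informative progeny are flagged and left
    unchanged.  Returns the corrected dosage vector and a report table.
    """
    offspring = ped.offspring_of(focal_parent)
    if not offspring:
        raise ValueError(f"{focal_parent!r} has no offspring in the pedigree")
    obs = _observation_probs(epsilon)
    dose_p = offspring_dosage_probs()
    # loglik[g_focal, g_other, o_obs]; o index 3 = missing contributes 0
    ll = np.zeros((3, 4, 4))
    for g in range(3):
        for go in range(3):
            p_obs = dose_p[g, go] @ obs  # P(observed o | g, go)
            ll[g, go, :3] = np.log(np.clip(p_obs, 1e-300, None))
        # other parent missing at this marker: marginalise uniformly
        p_marg = np.mean([dose_p[g, go] @ obs for go in range(3)], axis=0)
        ll[g, 3, :3] = np.log(np.clip(p_marg, 1e-300, None))
    if marginalize_other:
        ll[:, :3, :] = ll[:, 3:4, :]

    O = np.stack([geno.row(o) for o in offspring])            # noqa: E741
    GO = np.stack([geno.row(ped.other_parent(o, focal_parent)) for o in offspring])
    O_idx = np.where(O < 0, 3, O)
    GO_idx = np.where(GO < 0, 3, GO)
    informative = (O >= 0)
    n_prog = informative.sum(axis=0)

    logliks = np.stack([ll[g, GO_idx, O_idx].sum(axis=0) for g in range(3)])
    best_g = logliks.argmax(axis=0).astype(np.int8)
    sorted_ll = np.sort(logliks, axis=0)
    second_margin = sorted_ll[2] - sorted_ll[1]

    original = geno.row(focal_parent).copy()
    corrected = original.copy()
    flagged = n_prog < min_family
    rows = []
    for j in np.flatnonzero(~flagged):
        old = int(original[j])
        new = int(best_g[j])
        if old == new:
            continue
        if old < 0:
            # imputation of a missing call: require separation from runner-up
            if second_margin[j] > margin:
                corrected[j] = new
                rows.append((j, old, new, float(second_margin[j]), int(n_prog[j]), "imputed"))
        else:
            gain = float(logliks[new, j] - logliks[old, j])
            if gain > margin:
                corrected[j] = new
                rows.append((j, old, new, gain, int(n_prog[j]), "corrected"))
    report = pd.DataFrame(rows, columns=["marker_idx", "old", "new", "margin", "n_progeny", "action"])
    if len(report):
        report.insert(0, "pos", geno.markers["pos"].to_numpy()[report["marker_idx"]])
        report.insert(0, "chrom", geno.markers["chrom"].to_numpy()[report["marker_idx"]])
    report.attrs["n_flagged_low_family"] = int(flagged.sum())
    return corrected, report


def count_mendelian_violations(
    geno: GenotypeMatrix, ped: Pedigree, focal_parent: str, focal_dosage: np.ndarray
) -> int:
    """Trio-violation count over the focal parent's half-sib family with a
    supplied focal dosage vector (used to check corrections never hurt)."""
    total = 0
    for o in ped.offspring_of(focal_parent):
        od = geno.row(o)
        go = geno.row(ped.other_parent(o, focal_parent))
        complete = (od >= 0) & (go >= 0) & (focal_dosage >= 0)
        total += int((~_CONSISTENT[focal_dosage[complete], go[complete], od[complete]]).sum())
    return total
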