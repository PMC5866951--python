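"""Two-step SNP validation in an outbred F1 pseudo-testcross family.

A pseudo-testcross between two heterozygous outbred parents segregates
1:1 at loci where one parent is heterozygous (het x hom testcross
configuration) and 1:2:1 where both are.  Discovery-panel loci are first
required to show all three diploid genotype classes; candidate loci are
then tested for strict adherence to the applicable Mendelian ratio with a
Pearson chi-square test in the mapping family.  Loci that fail or are
absent in the family may still be rescued when the discovery panel calls
them reliably (no missing data) with a homozygous class present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import MISSING, GenotypeMatrix, MatrixError

MODELS = {
    "1:1": np.array([0.5, 0.5]),
    "1:2:1": np.array([0.25, 0.5, 0.25]),
}


@dataclass
class SegregationResult:
    locus: str
    model: str  # "1:1" or "1:2:1"
    observed: tuple[int, ...]
    chi2: float
    df: int
    p_value: float
    passed: bool


def has_three_classes(column: np.ndarray) -> bool:
    """True when hom-ref, het and hom-alt all occur among non-missing calls."""
    column = np.asarray(column)
    obs = set(column[column != MISSING].tolist())
    return {0, 1, 2} <= obs


def segregation_test(
    counts,
    model: str,
    alpha: float = 0.001,
    locus: str = "",
) -> SegregationResult:
    """Pearson chi-square goodness of fit against a Mendelian ratio.

    ``counts`` are the observed genotype-class counts: two classes for
    1:1 (testcross), three for 1:2:1.  No continuity correction.  The locus
    passes when ``p >= alpha``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODELS)}")
    expected_props = MODELS[model]
    counts = np.asarray(counts, dtype=float)
    if counts.shape != expected_props.shape:
        raise ValueError(
            f"model {model} expects {len(expected_props)} classes, got {len(counts)}"
        )
    if (counts < 0).any():
        raise ValueError("negative class counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("no observations")
    chi2, p = stats.chisquare(counts, f_exp=expected_props * total)
    df = len(counts) - 1
    return SegregationResult(
        locus=locus,
        model=model,
        observed=tuple(int(c) for c in counts),
        chi2=float(chi2),
        df=df,
        p_value=float(p),
        passed=bool(p >= alpha),
    )


def model_from_parents(parent1: int, parent2: int) -> str | None:
    """Applicable segregation model given the two parental genotypes.

    Both parents heterozygous -> 1:2:1; exactly one heterozygous (other
    homozygous) -> 1:1; anything else (no segregation expected, or missing
    parents) -> None.
    """
    if parent1 == MISSING or parent2 == MISSING:
        return None
    hets = (parent1 == 1) + (parent2 == 1)
    if hets == 2:
        return "1:2:1"
    if hets == 1:
        return "1:1"
    return None


def _class_counts(column: np.ndarray, model: str, parents: tuple[int, int]) -> np.ndarray:
    obs = column[column != MISSING]
    if model == "1:2:1":
        return np.array([(obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()])
    # 1:1 testcross: expected classes are the homozygote matching the
    # homozygous parent and the heterozygote
    hom_parent = parents[0] if parents[1] == 1 else parents[1]
    hom_class = 0 if hom_parent == 0 else 2
    return np.array([(obs == hom_class).sum(), (obs == 1).sum()])


def segregation_scan(
    genotypes: GenotypeMatrix,
    parents: dict[str, tuple[int, int]],
    model: str = "auto",
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Run the segregation test across a progeny genotype matrix.

    ``parents`` maps locus -> (parent1 call, parent2 call); with
    ``model='auto'`` the applicable ratio is chosen from the parents and
    inapplicable loci are reported with model 'none' and no test.
    Missing progeny calls are excluded from the class counts.
    """
    records = []
    for i, locus in enumerate(genotypes.loci):
        par = parents.get(locus, (MISSING, MISSING))
        m = model_from_parents(*par) if model == "auto" else model
        if m is None:
            records.append(
                {"locus": locus, "model": "none", "chi2": np.nan, "df": 0,
                 "p_value": np.nan, "passed": False}
            )
            continue
        counts = _class_counts(genotypes.data[i], m, par)
        if counts.sum() == 0:
            records.append(
                {"locus": locus, "model": m, "chi2": np.nan, "df": len(counts) - 1,
                 "p_value": np.nan, "passed": False}
            )
            continue
        res = segregation_test(counts, m, alpha=alpha, locus=locus)
        records.append(
            {"locus": locus, "model": m, "chi2": res.chi2, "df": res.df,
             "p_value": res.p_value, "passed": res.passed}
        )
    return pd.DataFrame.from_records(records)


def assemble_highconf(
    discovery: GenotypeMatrix,
    mapping_results: pd.DataFrame,
) -> tuple[list[str], dict[str, int]]:
    """Union of segregation-validated loci and reliably-called rescues.

    A rescue locus failed (or was never tested in) the mapping family but
    is called in *every* discovery-panel sample with at least one
    homozygous class present.  Returns the retained loci (discovery order)
    and the contribution counts.
    """
    passed = set(mapping_results.loc[mapping_results["passed"], "locus"])
    retained: list[str] = []
    n_rescued = 0
    for i, locus in enumerate(discovery.loci):
        if locus in passed:
            retained.append(locus)
            continue
        col = discovery.data[i]
        if (col == MISSING).any():
            continue
        if (col == 0).any() or (col == 2).any():
            retained.append(locus)
            n_rescued += 1
    # passed loci absent from the discovery matrix still belong to the union
    extra = [l for l in mapping_results.loc[mapping_results["passed"], "locus"]
             if l not in set(discovery.loci)]
    retained.extend(extra)
    counts = {
        "segregation_pass": len(passed),
        "rescued_homozygous": n_rescued,
        "total": len(retained),
    }
    return retained, counts
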