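"""Per-line consensus genotyping and retention classes for inbred panels.

Inbred diploid panels (single-seed-descent lines at roughly the F7/F8
generation) are genotyped with several seedlings per line.  Each line gets
a consensus call per locus — the modal genotype among its seedlings — and
loci are then retained under three mutually exclusive classes, in priority
order:

``both-homozygous``
    both homozygous classes (0 and 2) appear among the consensus calls —
    the high-confidence set;
``one-hom-plus-het``
    only one homozygous class, but at least four lines have a heterozygous
    consensus;
``opposing-homs-within-line``
    neither of the above, but some single line's seedlings contain both
    homozygous classes (a segregating or residually heterozygous line);
``rejected``
    everything else.

The priority makes the class counts additive: the retained total is the sum
of the three retained class sizes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import MISSING, GenotypeMatrix, MatrixError, SampleMap

RETAINED_CLASSES = ("both-homozygous", "one-hom-plus-het", "opposing-homs-within-line")


@dataclass
class ConsensusResult:
    """Loci x lines consensus matrix plus per-entry seedling support."""

    matrix: GenotypeMatrix  # entries are consensus calls per line
    support: np.ndarray  # number of non-missing seedlings behind each entry

    @property
    def lines(self) -> list[str]:
        return self.matrix.samples


def line_consensus(calls: np.ndarray) -> int:
    """Modal non-missing genotype of one line's seedlings at one locus.

    All-missing or a tie for the mode yields missing — determinism is
    preferred over coverage.
    """
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        return MISSING
    counts = Counter(obs.tolist())
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return MISSING
    return int(top[0][0])


def build_consensus(genotypes: GenotypeMatrix, linemap: SampleMap) -> ConsensusResult:
    """Collapse seedlings to one consensus column per line."""
    linemap.check_covers(genotypes.samples, "line")
    lines = linemap.lines()
    cols = {
        ln: [j for j, s in enumerate(genotypes.samples) if linemap.line[s] == ln]
        for ln in lines
    }
    data = np.full((genotypes.n_loci, len(lines)), MISSING, dtype=np.int16)
    support = np.zeros((genotypes.n_loci, len(lines)), dtype=np.int16)
    for k, ln in enumerate(lines):
        sub = genotypes.data[:, cols[ln]]
        support[:, k] = (sub != MISSING).sum(axis=1)
        for i in range(genotypes.n_loci):
            data[i, k] = line_consensus(sub[i])
    return ConsensusResult(GenotypeMatrix(list(genotypes.loci), lines, data), support)


def classify_locus(
    consensus_calls: np.ndarray,
    within_line_calls: dict[str, np.ndarray] | None = None,
    min_het_lines: int = 4,
) -> str:
    """Assign the retention class of one locus (priority order as listed
    in the module docstring)."""
    consensus_calls = np.asarray(consensus_calls)
    if consensus_calls.size == 0:
        raise MatrixError("empty consensus for locus")
    obs = consensus_calls[consensus_calls != MISSING]
    has0 = bool((obs == 0).any())
    has2 = bool((obs == 2).any())
    if has0 and has2:
        return "both-homozygous"
    n_het = int((obs == 1).sum())
    if (has0 or has2) and n_het >= min_het_lines:
        return "one-hom-plus-het"
    if within_line_calls:
        for calls in within_line_calls.values():
            calls = np.asarray(calls)
            seen = calls[calls != MISSING]
            if (seen == 0).any() and (seen == 2).any():
                return "opposing-homs-within-line"
    return "rejected"


def classify_panel(
    genotypes: GenotypeMatrix,
    linemap: SampleMap,
    min_het_lines: int = 4,
) -> pd.DataFrame:
    """Classify every locus; returns a table with the class label and
    supporting consensus-class counts per locus."""
    cons = build_consensus(genotypes, linemap)
    lines = cons.lines
    cols = {
        ln: [j for j, s in enumerate(genotypes.samples) if linemap.line[s] == ln]
        for ln in lines
    }
    records = []
    for i, locus in enumerate(genotypes.loci):
        within = {ln: genotypes.data[i, cols[ln]] for ln in lines}
        label = classify_locus(cons.matrix.data[i], within, min_het_lines)
        row = cons.matrix.data[i]
        records.append(
            {
                "locus": locus,
                "class": label,
                "n_hom_ref": int((row == 0).sum()),
                "n_het": int((row == 1).sum()),
                "n_hom_alt": int((row == 2).sum()),
                "n_missing": int((row == MISSING).sum()),
            }
        )
    return pd.DataFrame.from_records(records)


def retained_set(classification: pd.DataFrame) -> list[str]:
    """Loci in any retained class.  Classes are disjoint by the priority
    rule, so the cardinality equals the sum of the three class counts."""
    keep = classification["class"].isin(RETAINED_CLASSES)
    return classification.loc[keep, "locus"].tolist()


def line_heterogeneity(consensus_calls: np.ndarray) -> float:
    """Fraction of one line's non-missing consensus calls that are
    heterozygous — the residual heterozygosity surviving inbreeding."""
    consensus_calls = np.asarray(consensus_calls)
    obs = consensus_calls[consensus_calls != MISSING]
    if obs.size == 0:
        raise MatrixError("all consensus calls missing for line")
    return float((obs == 1).mean())


def panel_heterogeneity(consensus: ConsensusResult) -> float:
    """Mean within-line heterogeneity over all lines of a panel."""
    vals = [line_heterogeneity(consensus.matrix.data[:, k]) for k in range(len(consensus.lines))]
    return float(np.mean(vals))
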