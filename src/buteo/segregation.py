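"""Mendelian segregation analysis of the three-morph colour scheme.

The one-locus two-allele hypothesis treats dark (D) and light (L) morphs as
the two homozygotes and the intermediate (I) morph as the heterozygote, so
offspring morph probabilities for each parental combination follow from
gamete enumeration. This module maps the seven-point field score to the
three classes, tabulates observed parent->offspring crosses, and provides
exact and resampling tests of the observed counts against the Mendelian
expectation, including a family-level bootstrap that respects the
non-independence of offspring raised by the same pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "MORPHS",
    "COMBINATIONS",
    "MorphScheme",
    "SCENARIOS",
    "map_morph",
    "expected_segregation",
    "CrossTable",
    "tabulate_crosses",
    "TestResult",
    "goodness_of_fit",
    "compare_crosses",
    "family_bootstrap_test",
    "reconstruct_counts",
    "STUDY_OBSERVED",
    "study_cross_table",
]

log = logging.getLogger(__name__)

MORPHS = ("D", "I", "L")
#: unordered parental morph combinations, canonical order
COMBINATIONS = ("DxD", "DxI", "DxL", "IxI", "IxL", "LxL")


def combo_key(m1: str, m2: str) -> str:
    """Canonical unordered label, e.g. ('L', 'D') -> 'DxL'."""
    a, b = sorted((m1, m2), key=MORPHS.index)
    return f"{a}x{b}"


@dataclass(frozen=True)
class MorphScheme:
    """A lumping of the seven-point score into the D/I/L scheme.

    The mapping must be total on 1..7, monotone (a lighter score never maps
    to a darker class) and pin the extremes: 1 -> D, 7 -> L.
    """

    scenario_id: str
    mapping: Mapping[int, str]

    def __post_init__(self):
        if set(self.mapping) != set(range(1, 8)):
            raise ValueError("mapping must cover scores 1..7 exactly")
        if self.mapping[1] != "D" or self.mapping[7] != "L":
            raise ValueError("extremes must map to extremes (1 -> D, 7 -> L)")
        ranks = [MORPHS.index(self.mapping[s]) for s in range(1, 8)]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("mapping must be monotone from dark to light")

    @classmethod
    def from_bands(cls, scenario_id: str, dark_max: int, light_min: int) -> "MorphScheme":
        """Scheme with D = 1..dark_max, I = dark_max+1..light_min-1, L = light_min..7."""
        mapping = {
            s: "D" if s <= dark_max else ("L" if s >= light_min else "I")
            for s in range(1, 8)
        }
        return cls(scenario_id, mapping)


#: Four alternative lumping scenarios of the seven-point scale. Scenario "1"
#: is the default ({1,2} dark, {3,4,5} intermediate, {6,7} light); the others
#: shift the class boundaries and are placeholders to be overridden with any
#: published scenario definition.
SCENARIOS: dict[str, MorphScheme] = {
    "1": MorphScheme.from_bands("1", dark_max=2, light_min=6),
    "2": MorphScheme.from_bands("2", dark_max=3, light_min=6),
    "3": MorphScheme.from_bands("3", dark_max=2, light_min=5),
    "4": MorphScheme.from_bands("4", dark_max=3, light_min=5),
}


def map_morph(morph7: int, scheme: MorphScheme) -> str:
    """Class of a seven-point score under the given lumping scenario."""
    if morph7 not in scheme.mapping:
        raise ValueError(f"morph7 score out of range 1..7: {morph7}")
    return scheme.mapping[morph7]


# -- Mendelian expectation -----------------------------------------------------

_GENOTYPE = {"D": (1, 1), "I": (1, 0), "L": (0, 0)}  # allele 1 = dark


def expected_segregation(p1: str, p2: str) -> tuple[float, float, float]:
    """Expected offspring (D, I, L) percentages under one locus, two alleles.

    D and L parents are taken as the opposite homozygotes and I as the
    heterozygote; offspring class probabilities come from enumerating
    parental gametes. Symmetric in the parents; the triple sums to 100.
    """
    for p in (p1, p2):
        if p not in MORPHS:
            raise ValueError(f"unknown morph class {p!r}")
    probs = {2: Fraction(0), 1: Fraction(0), 0: Fraction(0)}
    g1, g2 = _GENOTYPE[p1], _GENOTYPE[p2]
    for a1, a2 in itertools.product(g1, g2):
        probs[a1 + a2] += Fraction(1, 4)
    return (float(100 * probs[2]), float(100 * probs[1]), float(100 * probs[0]))


# -- observed cross tables -----------------------------------------------------


@dataclass
class CrossTable:
    """Offspring morph counts per unordered parental combination.

    ``counts`` is indexed by the six combination labels with integer columns
    ``n_D``, ``n_I``, ``n_L``; ``n_skipped`` counts offspring dropped because
    they or a parent lacked a score.
    """

    counts: pd.DataFrame
    n_skipped: int = 0

    @classmethod
    def empty(cls) -> "CrossTable":
        frame = pd.DataFrame(
            0, index=list(COMBINATIONS), columns=[f"n_{m}" for m in MORPHS], dtype=int
        )
        frame.index.name = "parents"
        return cls(frame)

    @classmethod
    def from_counts(cls, counts: Mapping[str, tuple[int, int, int]]) -> "CrossTable":
        ct = cls.empty()
        for combo, triple in counts.items():
            if combo not in COMBINATIONS:
                raise ValueError(f"unknown parental combination {combo!r}")
            if min(triple) < 0:
                raise ValueError("offspring counts must be non-negative")
            ct.counts.loc[combo] = list(triple)
        return ct

    def n_offspring(self, combo: str) -> int:
        return int(self.counts.loc[combo].sum())

    def observed(self, combo: str) -> np.ndarray:
        return self.counts.loc[combo].to_numpy()

    def percentages(self) -> pd.DataFrame:
        """Per-combination offspring percentages (NaN where N = 0)."""
        totals = self.counts.sum(axis=1)
        return 100 * self.counts.div(totals.where(totals > 0), axis=0)


def tabulate_crosses(ped: Pedigree, scheme: MorphScheme) -> CrossTable:
    """Tally scored offspring by the unordered morph classes of their parents.

    Offspring missing a score, a parent, or a parent's score are skipped and
    counted in ``n_skipped`` (logged as a warning when any are dropped).
    """
    ct = CrossTable.empty()
    t = ped.table
    morph = dict(zip(t["id"], t["morph7"]))
    skipped = 0
    for _, row in t.iterrows():
        trio = (row["morph7"], morph.get(row["sire"]), morph.get(row["dam"]))
        if row["sire"] is None or row["dam"] is None or any(pd.isna(v) for v in trio):
            if not pd.isna(row["morph7"]) and (row["sire"] or row["dam"]):
                skipped += 1
            continue
        off, sm, dm = (map_morph(int(v), scheme) for v in trio)
        ct.counts.loc[combo_key(sm, dm), f"n_{off}"] += 1
    if skipped:
        log.warning("tabulate_crosses: skipped %d offspring lacking a scored parent", skipped)
    ct.n_skipped = skipped
    return ct


# -- published cross table -----------------------------------------------------

#: Observed offspring-morph percentages and totals per parental combination
#: from the long-term Friesland (NL) common-buzzard population study
#: (seven-point scores lumped under scenario 1): {combo: (N, %D, %I, %L)}.
STUDY_OBSERVED: dict[str, tuple[int, float, float, float]] = {
    "DxD": (97, 83.5, 16.5, 0.0),
    "DxI": (350, 47.1, 48.3, 4.6),
    "DxL": (32, 18.7, 43.8, 37.5),
    "IxI": (258, 15.1, 74.0, 10.9),
    "IxL": (138, 2.9, 31.9, 65.2),
    "LxL": (94, 1.1, 14.9, 84.0),
}


def reconstruct_counts(percentages: tuple[float, float, float], n: int) -> tuple[int, ...]:
    """Recover integer counts from printed percentages of a known total.

    Each count is round(pct * n / 100); the result must reproduce the printed
    percentage to within 0.05 (printed tables round half-cases either way)
    and the counts must sum to ``n``, otherwise the table is inconsistent.
    """
    counts = tuple(int(round(p * n / 100.0)) for p in percentages)
    for c, p in zip(counts, percentages):
        if abs(100.0 * c / n - p) > 0.05 + 1e-9:
            raise ValueError(
                f"count {c}/{n} does not reproduce printed percentage {p} at 1 decimal"
            )
    if sum(counts) != n:
        raise ValueError(f"reconstructed counts {counts} do not sum to N={n}")
    return counts


def study_cross_table() -> CrossTable:
    """The published Friesland cross table reconstructed as integer counts."""
    return CrossTable.from_counts(
        {combo: reconstruct_counts(row[1:], row[0]) for combo, row in STUDY_OBSERVED.items()}
    )


# -- tests ---------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_resamples: int | None = None
    seed: int | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def _pearson_statistic(observed: np.ndarray, probs: np.ndarray) -> float:
    n = observed.sum()
    expected = n * probs
    if np.any((expected == 0) & (observed > 0)):
        return float("inf")
    ok = expected > 0
    return float(np.sum((observed[ok] - expected[ok]) ** 2 / expected[ok]))


def _enumerate_outcomes(n: int) -> np.ndarray:
    """All (n_D, n_I, n_L) with the given total, shape (m, 3)."""
    d, i = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = d + i <= n
    return np.stack([d[keep], i[keep], n - d[keep] - i[keep]], axis=1)


def goodness_of_fit(
    ct: CrossTable,
    expected: Mapping[str, tuple[float, float, float]],
    combo: str,
    method: str = "exact",
    n_resamples: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Test one parental combination's offspring counts against expectation.

    ``expected`` maps combination labels to (D, I, L) percentage triples.
    Methods:

    - ``"exact"``: exact multinomial test; p is the total probability of all
      outcomes no more probable than the observed one (ties included). An
      observed count in a zero-probability class gives p = 0 exactly.
    - ``"monte-carlo"``: same ordering, estimated from ``n_resamples``
      multinomial draws with the add-one correction
      (1 + #{at least as extreme}) / (1 + n_resamples); requires ``seed``.
    - ``"pearson"``: Pearson chi-square with the asymptotic reference
      distribution (zero-probability classes: any observation there gives
      p = 0, otherwise the class is dropped from the statistic).
    """
    observed = ct.observed(combo)
    n = int(observed.sum())
    if n == 0:
        raise ValueError(f"no offspring observed for combination {combo}")
    probs = np.asarray(expected[combo], dtype=float) / 100.0
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("expected percentages must sum to 100")
    stat = _pearson_statistic(observed, probs)

    if method == "exact":
        outcomes = _enumerate_outcomes(n)
        pmf = stats.multinomial(n, probs).pmf(outcomes)
        p_obs = float(stats.multinomial(n, probs).pmf(observed))
        p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum()) if p_obs > 0 else 0.0
        return TestResult(stat, min(p, 1.0), "exact-multinomial")
    if method == "monte-carlo":
        if seed is None:
            raise ValueError("monte-carlo method requires a seed (reproducibility)")
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(n, probs, size=n_resamples)
        pmf = stats.multinomial(n, probs).pmf(draws)
        p_obs = float(stats.multinomial(n, probs).pmf(observed))
        extreme = int((pmf <= p_obs * (1 + 1e-12)).sum())
        p = (1 + extreme) / (1 + n_resamples)
        return TestResult(stat, p, "monte-carlo-chi2", n_resamples, seed)
    if method == "pearson":
        if np.isinf(stat):
            return TestResult(stat, 0.0, "pearson-chi2")
        df = int((probs > 0).sum()) - 1
        return TestResult(stat, float(stats.chi2.sf(stat, df)), "pearson-chi2")
    raise ValueError(f"unknown method {method!r}")


def compare_crosses(
    ct: CrossTable,
    combo_a: str,
    combo_b: str,
    focal_morph: str = "I",
    method: str = "pearson",
) -> TestResult:
    """Two-sided test that the focal-morph offspring proportion differs
    between two parental combinations (2x2 table: focal vs non-focal).

    ``method`` is ``"pearson"`` (chi-square without continuity correction) or
    ``"exact"`` (conditional/Fisher). A degenerate margin (every offspring in
    one category) yields p = 1 with a warning.
    """
    rows = []
    for combo in (combo_a, combo_b):
        n = ct.n_offspring(combo)
        if n == 0:
            raise ValueError(f"no offspring observed for combination {combo}")
        focal = int(ct.counts.loc[combo, f"n_{focal_morph}"])
        rows.append([focal, n - focal])
    table = np.array(rows)
    if np.any(table.sum(axis=0) == 0):
        log.warning("compare_crosses: degenerate margin, test uninformative")
        return TestResult(0.0, 1.0, method, detail={"table": table.tolist()})
    if method == "pearson":
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return TestResult(float(stat), float(p), "pearson-chi2", detail={"table": table.tolist()})
    if method == "exact":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return TestResult(float(odds), float(p), "exact-conditional", detail={"table": table.tolist()})
    raise ValueError(f"unknown method {method!r}")


def _family_focal_counts(
    ped: Pedigree, scheme: MorphScheme, combo: str, focal_morph: str
) -> np.ndarray:
    """Per-family (n_offspring, n_focal) for families of the given combination."""
    t = ped.table
    morph = dict(zip(t["id"], t["morph7"]))
    fams: dict[tuple[str, str], list[int]] = {}
    for _, row in t.iterrows():
        trio = (row["morph7"], morph.get(row["sire"]), morph.get(row["dam"]))
        if row["sire"] is None or row["dam"] is None or any(pd.isna(v) for v in trio):
            continue
        off, sm, dm = (map_morph(int(v), scheme) for v in trio)
        if combo_key(sm, dm) != combo:
            continue
        fams.setdefault((row["sire"], row["dam"]), []).append(int(off == focal_morph))
    return np.array([[len(v), sum(v)] for v in fams.values()], dtype=float)


def family_bootstrap_test(
    ped: Pedigree,
    scheme: MorphScheme,
    combo_a: str,
    combo_b: str,
    focal_morph: str = "I",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Family-level bootstrap of the focal-morph proportion difference.

    Count tests treat offspring as independent, but siblings share a nest and
    parents; resampling whole families (pairs) with replacement within each
    parental combination propagates that clustering into the null. The
    two-sided p-value is min(1, 2 * min(#{d* <= 0}, #{d* >= 0}) / n_boot)
    where d* is the bootstrap difference in focal proportions.
    """
    if seed is None:
        raise ValueError("family bootstrap requires a seed (reproducibility)")
    fam_a = _family_focal_counts(ped, scheme, combo_a, focal_morph)
    fam_b = _family_focal_counts(ped, scheme, combo_b, focal_morph)
    for combo, fams in ((combo_a, fam_a), (combo_b, fam_b)):
        if len(fams) < 2:
            raise ValueError(f"fewer than 2 families in combination {combo}")
    rng = np.random.default_rng(seed)

    def resample(fams: np.ndarray) -> np.ndarray:
        idx = rng.integers(0, len(fams), size=(n_boot, len(fams)))
        tot = fams[idx, 0].sum(axis=1)
        foc = fams[idx, 1].sum(axis=1)
        return np.where(tot > 0, foc / np.maximum(tot, 1), np.nan)

    d_star = resample(fam_a) - resample(fam_b)
    d_star = d_star[np.isfinite(d_star)]
    d_obs = fam_a[:, 1].sum() / fam_a[:, 0].sum() - fam_b[:, 1].sum() / fam_b[:, 0].sum()
    lo = int((d_star <= 0).sum())
    hi = int((d_star >= 0).sum())
    p = min(1.0, 2.0 * min(lo, hi) / len(d_star))
    return TestResult(float(d_obs), p, "family-bootstrap", n_boot, seed)
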