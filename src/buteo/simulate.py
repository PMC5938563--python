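"""Study-emulating synthetic pedigrees and phenotypes.

The generator mimics the structure of the long-term buzzard population data
the analyses were designed for: a two-generation pedigree of roughly 202
breeding pairs whose re-pairing across years produces half-sib families
(about 292 distinct parents and 989 scored offspring, fathers averaging 6.7
offspring with range 1-31), and seven-point colour scores produced under
either of the two competing inheritance models — a one-locus two-allele
codominant model or a polygenic liability model cut at ordered thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, write_pedigree

__all__ = [
    "PedigreeSimConfig",
    "MendelianSimConfig",
    "PolygenicSimConfig",
    "simulate_pedigree",
    "simulate_mendelian",
    "simulate_polygenic",
    "make_fixture",
    "FIXTURES",
]

#: morph7 bands per three-morph class; mirrors lumping scenario 1 so that
#: map_morph inverts the simulation exactly
MORPH7_BANDS = {"D": (1, 2), "I": (3, 4, 5), "L": (6, 7)}


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Breeding-structure settings.

    Defaults emulate the study population: 202 breeding pairs (families)
    with zero-truncated negative-binomial family sizes (mean 5.2, calibrated
    so that after per-parent caps ~989 offspring remain from ~300 distinct
    parents). ``re_pairing_rate`` is the
    probability that a parent appears in multiple pairs; such serial
    breeders hold 2 + Poisson(``extra_mates_mean``) pairs, which produces
    the long-tailed per-parent offspring totals of a multi-year territory
    system (fathers averaging ~6.7 offspring, range capped at 31) and hence
    abundant half-sib links. Breeding is spread over ``n_years`` with broods
    of at most ``max_brood`` chicks; each pair-year is one nest.
    """

    n_pairs: int = 202
    family_size_mean: float = 5.2
    family_size_dispersion: float = 1.4
    re_pairing_rate: float = 0.12
    extra_mates_mean: float = 2.5
    n_years: int = 16
    first_year: int = 2001
    max_offspring_per_parent: int = 31
    max_brood: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.family_size_mean <= 0:
            raise ValueError("family_size_mean must be positive")
        if not 0.0 <= self.re_pairing_rate < 1.0:
            raise ValueError("re_pairing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class MendelianSimConfig:
    """One-locus two-allele phenotype settings: founder dark-allele frequency
    and the probability that a true score is recorded one class off."""

    dark_allele_freq: float = 0.5
    misclassification_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.dark_allele_freq < 1.0:
            raise ValueError("dark_allele_freq must lie in (0, 1)")
        if not 0.0 <= self.misclassification_rate <= 1.0:
            raise ValueError("misclassification_rate must lie in [0, 1]")


def _default_thresholds() -> tuple[float, ...]:
    # placeholder; replaced in __post_init__ when user passes none
    return ()


@dataclass(frozen=True)
class PolygenicSimConfig:
    """Polygenic liability settings.

    Default variances are the study-scale partition (V_P = 2.24 split as
    V_A = 1.84, V_M = 0.13, V_F = 0.11, V_R = 0.16, i.e. h^2 = 0.82).
    ``thresholds`` are the six ordered cut-points mapping liability
    (centred at 0) to the seven-point score; the default cuts at the
    normal quantiles of cumulative (4, 15, 35, 65, 85, 96)% of the total
    variance, giving a unimodal, centred score distribution.
    """

    v_animal: float = 1.84
    v_mother: float = 0.13
    v_father: float = 0.11
    v_nest: float = 0.0
    v_year: float = 0.0
    v_resid: float = 0.16
    thresholds: tuple[float, ...] = field(default_factory=_default_thresholds)
    phenotype_founders: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("v_animal", "v_mother", "v_father", "v_nest", "v_year", "v_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.v_animal + self.v_resid <= 0:
            raise ValueError("at least one of v_animal, v_resid must be positive")
        if not self.thresholds:
            object.__setattr__(self, "thresholds", self.default_thresholds(self.v_total))
        thr = np.asarray(self.thresholds, dtype=float)
        if len(thr) != 6 or np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be 6 strictly increasing cut-points")

    @property
    def v_total(self) -> float:
        return (
            self.v_animal + self.v_mother + self.v_father
            + self.v_nest + self.v_year + self.v_resid
        )

    @staticmethod
    def default_thresholds(v_total: float) -> tuple[float, ...]:
        from scipy.stats import norm

        q = np.array([0.04, 0.15, 0.35, 0.65, 0.85, 0.96])
        return tuple(norm.ppf(q, scale=np.sqrt(v_total)))


# -- pedigree structure --------------------------------------------------------


def _zt_negbin(rng: np.random.Generator, mean: float, disp: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial via rejection; ``disp`` is the
    gamma-Poisson shape parameter (smaller = more overdispersed)."""
    out = np.zeros(size, dtype=int)
    todo = np.arange(size)
    while len(todo):
        lam = rng.gamma(disp, mean / disp, size=len(todo))
        draw = rng.poisson(lam)
        ok = draw > 0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _mate_slots(rng: np.random.Generator, cfg: PedigreeSimConfig, prefix: str) -> list[str]:
    """Parent ids repeated once per pair they hold; exactly n_pairs slots.

    Each new parent holds one pair, or — with probability re_pairing_rate —
    is a serial breeder holding 2 + Poisson(extra_mates_mean) pairs.
    """
    slots: list[str] = []
    k = 0
    while len(slots) < cfg.n_pairs:
        k += 1
        n_mates = 1
        if rng.random() < cfg.re_pairing_rate:
            n_mates = 2 + int(rng.poisson(cfg.extra_mates_mean))
        slots += [f"{prefix}{k:03d}"] * n_mates
    return slots[: cfg.n_pairs]


def simulate_pedigree(cfg: PedigreeSimConfig) -> Pedigree:
    """Generate a two-generation pedigree with re-pairing half-sib structure.

    Sire and dam pair-slots are generated per ``_mate_slots``, shuffled and
    matched one-to-one into ``n_pairs`` families. Each family gets a
    zero-truncated negative-binomial offspring count (trimmed so no parent
    exceeds ``max_offspring_per_parent``), split into broods of at most
    ``max_brood`` chicks in consecutive years; every pair-year is one nest.
    """
    rng = np.random.default_rng(cfg.seed)
    # underlying NB mean so that the zero-truncated mean matches family_size_mean
    disp = cfg.family_size_dispersion
    mu = cfg.family_size_mean
    for _ in range(60):  # fixed-point: zt_mean(mu0) = mu0 / (1 - P0(mu0))
        p0 = (disp / (disp + mu)) ** disp
        mu_new = cfg.family_size_mean * (1.0 - p0)
        if abs(mu_new - mu) < 1e-10:
            break
        mu = mu_new

    sire_slots = _mate_slots(rng, cfg, "S")
    dam_slots = _mate_slots(rng, cfg, "D")
    rng.shuffle(sire_slots)
    rng.shuffle(dam_slots)
    pairs = list(dict.fromkeys(zip(sire_slots, dam_slots)))  # drop rare duplicate pairs

    sizes = _zt_negbin(rng, mu, disp, len(pairs))
    totals: dict[str, int] = {}
    rows = []
    n_off = 0
    for (sire, dam), k in zip(pairs, sizes):
        room = min(
            cfg.max_offspring_per_parent - totals.get(sire, 0),
            cfg.max_offspring_per_parent - totals.get(dam, 0),
        )
        k = int(min(k, max(room, 0)))
        if k == 0:
            continue
        totals[sire] = totals.get(sire, 0) + k
        totals[dam] = totals.get(dam, 0) + k
        n_broods = int(np.ceil(k / cfg.max_brood))
        start = int(rng.integers(0, max(cfg.n_years - n_broods, 0) + 1))
        brood_sizes = np.diff(np.linspace(0, k, n_broods + 1).round().astype(int))
        for b, bs in enumerate(brood_sizes):
            year = cfg.first_year + start + b
            nest = f"N_{sire}_{dam}_{year}"
            for _ in range(int(bs)):
                n_off += 1
                rows.append(
                    {"id": f"O{n_off:04d}", "sire": sire, "dam": dam,
                     "sex": "M" if rng.random() < 0.5 else "F",
                     "birth_year": year, "nest": nest, "morph7": None}
                )
    # parents whose every family was trimmed away leave no trace
    founders = [
        {"id": pid, "sire": None, "dam": None, "sex": "M" if pid.startswith("S") else "F",
         "birth_year": None, "nest": None, "morph7": None}
        for pid in sorted(totals)
    ]
    return Pedigree(pd.DataFrame(founders + rows))


# -- Mendelian phenotypes ------------------------------------------------------


def simulate_mendelian(ped: Pedigree, cfg: MendelianSimConfig) -> Pedigree:
    """Assign seven-point scores under the one-locus two-allele model.

    Founder genotypes (number of dark alleles) are Hardy-Weinberg draws at
    the configured allele frequency; each offspring receives one random
    allele per parent. Genotype fixes the three-morph class (2 -> D,
    1 -> I, 0 -> L); the seven-point score is uniform within the class band,
    then optionally misrecorded one point up or down.
    """
    rng = np.random.default_rng(cfg.seed)
    sidx, didx = ped.parent_indices()
    n = len(ped)
    geno = np.zeros(n, dtype=int)
    for i in range(n):
        s, d = sidx[i], didx[i]
        from_s = (
            rng.random() < cfg.dark_allele_freq if s < 0 else rng.random() < geno[s] / 2.0
        )
        from_d = (
            rng.random() < cfg.dark_allele_freq if d < 0 else rng.random() < geno[d] / 2.0
        )
        geno[i] = int(from_s) + int(from_d)

    classes = np.array(["L", "I", "D"])[geno]
    morph7 = np.empty(n, dtype=int)
    for cls, band in MORPH7_BANDS.items():
        mask = classes == cls
        morph7[mask] = rng.choice(band, size=int(mask.sum()))
    if cfg.misclassification_rate > 0:
        flip = rng.random(n) < cfg.misclassification_rate
        step = np.where(rng.random(n) < 0.5, -1, 1)
        morph7 = np.where(flip, np.clip(morph7 + step, 1, 7), morph7)

    table = ped.table.copy()
    table["morph7"] = morph7
    table["genotype_dark_alleles"] = geno
    return Pedigree(table)


# -- polygenic phenotypes ------------------------------------------------------


def simulate_polygenic(ped: Pedigree, cfg: PolygenicSimConfig) -> Pedigree:
    """Assign scores under the polygenic liability-threshold model.

    Founder breeding values are N(0, V_A); a non-founder inherits the
    parental average plus a Mendelian-sampling deviate (variance V_A/2 with
    two known non-inbred parents, 3V_A/4 with one, V_A for a founder).
    Maternal, paternal, nest and year effects are iid normal with their
    variances; liability = breeding value + those effects + residual, and
    the seven-point score is the liability's bin among the thresholds. The
    continuous liability is kept in a ``liability`` column for diagnostics.
    """
    rng = np.random.default_rng(cfg.seed)
    sidx, didx = ped.parent_indices()
    n = len(ped)

    a = np.empty(n)
    for i in range(n):
        s, d = sidx[i], didx[i]
        if s >= 0 and d >= 0:
            a[i] = 0.5 * (a[s] + a[d]) + rng.standard_normal() * np.sqrt(cfg.v_animal / 2.0)
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            a[i] = 0.5 * a[p] + rng.standard_normal() * np.sqrt(0.75 * cfg.v_animal)
        else:
            a[i] = rng.standard_normal() * np.sqrt(cfg.v_animal)

    t = ped.table
    liab = a.copy()
    # individuals with an unrecorded mother/father/nest/year still experience
    # such an effect — it is simply unshared, so they get their own draw
    for col, v in (("dam", cfg.v_mother), ("sire", cfg.v_father), ("nest", cfg.v_nest)):
        labels = [
            lv if isinstance(lv, str) else f"__own_{k}" for k, lv in enumerate(t[col])
        ]
        effects = {lv: rng.standard_normal() * np.sqrt(v) for lv in dict.fromkeys(labels)}
        liab += np.array([effects[lv] for lv in labels])
    years = [lv if not pd.isna(lv) else f"__own_{k}" for k, lv in enumerate(t["birth_year"])]
    year_eff = {lv: rng.standard_normal() * np.sqrt(cfg.v_year) for lv in dict.fromkeys(years)}
    liab += np.array([year_eff[lv] for lv in years])
    liab += rng.standard_normal(n) * np.sqrt(cfg.v_resid)

    morph7 = np.searchsorted(np.asarray(cfg.thresholds), liab) + 1
    table = t.copy()
    table["morph7"] = morph7
    table["liability"] = liab
    if not cfg.phenotype_founders:
        founders = table["sire"].isna() & table["dam"].isna()
        table.loc[founders, "morph7"] = pd.NA
    return Pedigree(table)


# -- fixtures ------------------------------------------------------------------


def _nuclear(seed: int) -> Pedigree:
    rows = [
        {"id": "S001", "sire": None, "dam": None, "sex": "M", "morph7": 3},
        {"id": "D001", "sire": None, "dam": None, "sex": "F", "morph7": 4},
        {"id": "O0001", "sire": "S001", "dam": "D001", "sex": "F", "morph7": 3},
        {"id": "O0002", "sire": "S001", "dam": "D001", "sex": "M", "morph7": 2},
        {"id": "O0003", "sire": "S001", "dam": "D001", "sex": "F", "morph7": 6},
    ]
    for row in rows:
        row.setdefault("birth_year", 2001 if row["sire"] else None)
        row.setdefault("nest", "N1" if row["sire"] else None)
    return Pedigree(pd.DataFrame(rows))


def halfsib_pedigree(n_sires: int = 100, offspring_per_sire: int = 20, seed: int = 0) -> Pedigree:
    """Balanced paternal half-sib design: each sire mated to as many dams as
    offspring, one chick per dam (classic sire-model layout)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_sires + 1):
        rows.append({"id": f"S{s:03d}", "sire": None, "dam": None, "sex": "M"})
    k = 0
    for s in range(1, n_sires + 1):
        for _ in range(offspring_per_sire):
            k += 1
            rows.append({"id": f"D{k:04d}", "sire": None, "dam": None, "sex": "F"})
            rows.append(
                {"id": f"O{k:04d}", "sire": f"S{s:03d}", "dam": f"D{k:04d}",
                 "sex": "M" if rng.random() < 0.5 else "F"}
            )
    return Pedigree(pd.DataFrame(rows))


def _study_mendelian(seed: int) -> Pedigree:
    ped = simulate_pedigree(PedigreeSimConfig(seed=seed))
    return simulate_mendelian(ped, MendelianSimConfig(seed=seed + 1))


def _study_polygenic(seed: int) -> Pedigree:
    ped = simulate_pedigree(PedigreeSimConfig(seed=seed))
    return simulate_polygenic(ped, PolygenicSimConfig(seed=seed + 1))


FIXTURES = {
    "nuclear": _nuclear,
    "halfsib_balanced": lambda seed: (
        simulate_polygenic(
            halfsib_pedigree(seed=seed),
            PolygenicSimConfig(v_mother=0.0, v_father=0.0, v_resid=0.40, phenotype_founders=False, seed=seed + 1),
        )
    ),
    "study_mendelian": _study_mendelian,
    "study_polygenic": _study_polygenic,
}


def make_fixture(name: str, out_dir: str | Path = ".", seed: int = 0) -> Path:
    """Write a named, seeded pedigree+phenotype CSV and return its path."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    ped = FIXTURES[name](seed)
    out = Path(out_dir) / f"{name}_seed{seed}.csv"
    write_pedigree(ped, out)
    return out
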