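"""Synthetic murine splenic TCR-beta cohorts with public/private architecture.

The generator emulates the repertoire structure that copy-number fractioning
exploits:

* **public clonotypes** — a pool of prototype clonotypes shared across
  animals: shorter CDR3, VJ pairs drawn from a concentrated (spiky)
  distribution, multiple nucleotide codings (convergent recombination), and
  copy numbers drawn from a flatter power law than private clones so they
  span all ten log2 fractions while having a much higher mean CN;
* **LD-1 satellites** — each prototype is surrounded by cluster neighbours
  at Levenshtein distance 1 that inherit its VJ pair and a correlated,
  somewhat lower copy number;
* **private clonotypes** — animal-unique random CDR3 sequences, mostly a
  single nucleotide coding, copy numbers from a steep power law (most at
  CN = 2);
* an injectable **immunization effect** — animal-unique specific private
  clonotypes inserted with copy numbers landing in a chosen range of log2
  fractions, diluting the public structure there (the displacement mechanism
  behind the early high-CN and late low-CN effects).

All randomness flows from one root seed through per-animal substreams
(``default_rng([seed, stream, animal_index])``), so cohorts are reproducible
and animals are independent.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .fractioning import LOG2_INTERVALS, log2_fraction_index
from .types import Clonotype, NucleotideVariant, Repertoire

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: standard codon table, inverted: amino acid -> codons
CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class EffectConfig:
    """Immunization effect: specific clones injected into chosen fractions."""

    target_fraction_lo: int = 7
    target_fraction_hi: int = 10
    n_specific_per_animal: int = 40
    expansion_multiplier: float = 1.0
    specific_type: str = "private"

    def __post_init__(self) -> None:
        if not (1 <= self.target_fraction_lo <= self.target_fraction_hi <= 10):
            raise ValueError("target fractions must satisfy 1 <= lo <= hi <= 10")
        if self.expansion_multiplier < 0:
            raise ValueError("expansion_multiplier must be >= 0")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Distributions and effect sizes for one labeled cohort."""

    n_control: int = 20
    n_treated: int = 10
    n_clonotypes_target: int = 3000
    # copy-number distributions: discrete power laws p(c) ~ c^-exponent on [cn_min, cn_max]
    cn_exponent_private: float = 2.5
    cn_exponent_public: float = 1.3
    cn_min: int = 2
    cn_max: int = 20000
    public_pool_size: int = 150
    public_share_prob: float = 0.8
    public_cn_multiplier: float = 1.0
    public_cdr3_length_shift: int = -2
    public_vj_concentration: float = 0.05
    public_nc_min: int = 2
    public_nc_poisson_mean: float = 1.5
    private_multi_coding_prob: float = 0.1
    satellite_multi_coding_prob: float = 0.7
    cluster_neighbors_per_public: int = 2
    cdr3_length_mode: int = 14
    cdr3_length_sd: float = 2.0
    cdr3_length_min: int = 8
    cdr3_length_max: int = 20
    n_v_segments: int = 20
    n_j_segments: int = 14
    effect: EffectConfig = field(default_factory=EffectConfig)
    conserve_reads: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.public_share_prob <= 1:
            raise ValueError("public_share_prob must be in [0, 1]")
        if self.public_cn_multiplier < 1:
            raise ValueError("public_cn_multiplier must be >= 1")
        if self.public_cdr3_length_shift > 0:
            raise ValueError("public_cdr3_length_shift must be <= 0")


@dataclass(frozen=True)
class PublicTemplate:
    cdr3_aa: str
    v_segment: str
    j_segment: str
    base_cn: int
    n_variants: int
    is_satellite: bool


@dataclass
class LabeledCohort:
    repertoires: list[Repertoire]
    labels: list[str]
    truth: dict[str, list[str]]  # sample_id -> injected specific cdr3_aa

    def controls(self) -> list[Repertoire]:
        return [r for r, l in zip(self.repertoires, self.labels) if l == "control"]

    def treated(self) -> list[Repertoire]:
        return [r for r, l in zip(self.repertoires, self.labels) if l == "immunized"]


# ---------------------------------------------------------------------------
# sampling helpers


@lru_cache(maxsize=16)
def _power_law_pmf(exponent: float, cn_min: int, cn_max: int):
    values = np.arange(cn_min, cn_max + 1)
    p = values.astype(np.float64) ** (-exponent)
    return values, p / p.sum()


def sample_power_law(
    rng: np.random.Generator, n: int, exponent: float, cn_min: int, cn_max: int
) -> np.ndarray:
    """Discrete power-law copy numbers via inverse-CDF sampling."""
    values, p = _power_law_pmf(exponent, cn_min, cn_max)
    idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
    return values[np.minimum(idx, len(values) - 1)]


def _draw_lengths(rng: np.random.Generator, n: int, cfg: SyntheticCohortConfig, shift: int = 0):
    raw = np.rint(rng.normal(cfg.cdr3_length_mode + shift, cfg.cdr3_length_sd, n))
    return np.clip(raw, cfg.cdr3_length_min, cfg.cdr3_length_max).astype(int)


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    """Random CDR3: canonical C...F frame with random core residues."""
    core = rng.integers(0, len(AMINO_ACIDS), size=length - 2)
    return "C" + "".join(AMINO_ACIDS[i] for i in core) + "F"


def reverse_translate(rng: np.random.Generator, aa: str) -> str:
    """One random nucleotide coding (uniform synonymous codon choice)."""
    counts = np.array([len(CODONS[a]) for a in aa])
    picks = rng.integers(0, counts)
    return "".join(CODONS[a][k] for a, k in zip(aa, picks))


def _distinct_codings(rng: np.random.Generator, aa: str, k: int) -> list[str]:
    """Up to k distinct nucleotide codings of one amino-acid sequence."""
    seen: list[str] = []
    seen_set: set[str] = set()
    attempts = 0
    while len(seen) < k and attempts < 10 * k + 20:
        nt = reverse_translate(rng, aa)
        if nt not in seen_set:
            seen.append(nt)
            seen_set.add(nt)
        attempts += 1
    return seen


def _split_reads(rng: np.random.Generator, total: int, k: int) -> np.ndarray:
    """Split ``total`` reads over k variants, each >= 1."""
    k = min(k, total)
    counts = np.ones(k, dtype=np.int64)
    if total > k:
        counts += rng.multinomial(total - k, np.full(k, 1.0 / k))
    return counts


def _make_clonotype(
    rng: np.random.Generator, aa: str, v: str, j: str, cn: int, n_variants: int
) -> Clonotype:
    codings = _distinct_codings(rng, aa, max(1, min(n_variants, cn)))
    reads = _split_reads(rng, cn, len(codings))
    variants = tuple(
        NucleotideVariant(nt, int(r)) for nt, r in zip(codings, reads)
    )
    return Clonotype(aa, v, j, int(cn), variants)


# ---------------------------------------------------------------------------
# public pool


def make_public_pool(config: SyntheticCohortConfig, seed: int | None = None) -> list[PublicTemplate]:
    """Prototype public clonotypes plus their LD-1 satellite neighbours.

    VJ pairs are drawn from a Dirichlet-categorical with small concentration,
    restricting public VJ usage to a handful of combinations. Satellites
    substitute one internal CDR3 residue, inherit the prototype's VJ pair and
    get a correlated, lower base copy number.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 1_000_003])
    v_names = [f"TRBV{i + 1}" for i in range(config.n_v_segments)]
    j_names = [f"TRBJ{i // 7 + 1}-{i % 7 + 1}" for i in range(config.n_j_segments)]
    n_combo = config.n_v_segments * config.n_j_segments
    vj_weights = rng.dirichlet(np.full(n_combo, config.public_vj_concentration))
    lengths = _draw_lengths(
        rng, config.public_pool_size, config, shift=config.public_cdr3_length_shift
    )
    base_cns = sample_power_law(
        rng, config.public_pool_size, config.cn_exponent_public, config.cn_min, config.cn_max
    )
    pool: list[PublicTemplate] = []
    used: set[str] = set()
    for i in range(config.public_pool_size):
        aa = _random_cdr3(rng, int(lengths[i]))
        while aa in used:
            aa = _random_cdr3(rng, int(lengths[i]))
        used.add(aa)
        combo = int(rng.choice(n_combo, p=vj_weights))
        v, j = v_names[combo // config.n_j_segments], j_names[combo % config.n_j_segments]
        n_var = config.public_nc_min + int(rng.poisson(config.public_nc_poisson_mean))
        pool.append(PublicTemplate(aa, v, j, int(base_cns[i]), n_var, False))
        for _ in range(config.cluster_neighbors_per_public):
            sat = _substitute_one(rng, aa)
            tries = 0
            while sat in used and tries < 50:
                sat = _substitute_one(rng, aa)
                tries += 1
            if sat in used:
                continue
            used.add(sat)
            sat_cn = max(2, int(round(base_cns[i] * 2.0 ** (-rng.uniform(0.0, 2.0)))))
            sat_var = 2 if rng.random() < config.satellite_multi_coding_prob else 1
            pool.append(PublicTemplate(sat, v, j, sat_cn, sat_var, True))
    return pool


def _substitute_one(rng: np.random.Generator, aa: str) -> str:
    """One random internal substitution (keeps the C...F frame)."""
    pos = int(rng.integers(1, len(aa) - 1))
    old = aa[pos]
    new = old
    while new == old:
        new = AMINO_ACIDS[int(rng.integers(0, len(AMINO_ACIDS)))]
    return aa[:pos] + new + aa[pos + 1 :]


# ---------------------------------------------------------------------------
# per-animal generation


def generate_repertoire(
    config: SyntheticCohortConfig,
    pool: list[PublicTemplate],
    animal_id: str,
    animal_index: int,
    group_label: str = "control",
    timepoint: str = "",
) -> Repertoire:
    """One animal: shared publics at jittered CN plus animal-unique privates."""
    rng = np.random.default_rng([config.seed, 2, animal_index])
    clonotypes: list[Clonotype] = []
    used: set[str] = set()
    # shared public clonotypes
    include = rng.random(len(pool)) < config.public_share_prob
    jitter = 2.0 ** rng.normal(0.0, 0.5, len(pool))
    for tmpl, inc, jit in zip(pool, include, jitter):
        if not inc:
            continue
        cn = max(2, int(round(tmpl.base_cn * jit * config.public_cn_multiplier)))
        cn = min(cn, config.cn_max)
        clonotypes.append(
            _make_clonotype(rng, tmpl.cdr3_aa, tmpl.v_segment, tmpl.j_segment, cn, tmpl.n_variants)
        )
        used.add(tmpl.cdr3_aa)
    # animal-unique private clonotypes
    n_private = max(0, config.n_clonotypes_target - len(clonotypes))
    lengths = _draw_lengths(rng, n_private, config)
    cns = sample_power_law(
        rng, n_private, config.cn_exponent_private, config.cn_min, config.cn_max
    )
    multi = rng.random(n_private) < config.private_multi_coding_prob
    v_idx = rng.integers(1, config.n_v_segments + 1, n_private)
    j_idx = rng.integers(0, config.n_j_segments, n_private)
    for i in range(n_private):
        aa = _random_cdr3(rng, int(lengths[i]))
        while aa in used:
            aa = _random_cdr3(rng, int(lengths[i]))
        used.add(aa)
        clonotypes.append(
            _make_clonotype(
                rng,
                aa,
                f"TRBV{v_idx[i]}",
                f"TRBJ{j_idx[i] // 7 + 1}-{j_idx[i] % 7 + 1}",
                int(cns[i]),
                2 if multi[i] else 1,
            )
        )
    return Repertoire(animal_id, clonotypes, group_label, timepoint)


def inject_effect(
    rep: Repertoire,
    effect: EffectConfig,
    config: SyntheticCohortConfig,
    animal_index: int,
) -> tuple[Repertoire, list[str]]:
    """Insert specific clonotypes with CN inside the targeted log2 fractions.

    Returns the modified repertoire and the injected CDR3 sequences (truth
    record). With ``config.conserve_reads`` the remaining clonotypes are
    hypergeometrically thinned so the total read count is unchanged.
    """
    rng = np.random.default_rng([config.seed, 3, animal_index])
    if effect.n_specific_per_animal == 0 or effect.expansion_multiplier == 0:
        return rep, []
    lo_f, hi_f = effect.target_fraction_lo, effect.target_fraction_hi
    cn_lo = int(LOG2_INTERVALS[lo_f - 1][0])  # exclusive lower bound
    hi_edge = LOG2_INTERVALS[hi_f - 1][1]
    cn_hi = int(hi_edge) if np.isfinite(hi_edge) else 2048
    if cn_lo + 1 > cn_hi:
        raise ValueError("infeasible target copy-number range")
    used = rep.aa_set()
    injected: list[Clonotype] = []
    truth: list[str] = []
    lengths = _draw_lengths(rng, effect.n_specific_per_animal, config)
    for i in range(effect.n_specific_per_animal):
        aa = _random_cdr3(rng, int(lengths[i]))
        while aa in used:
            aa = _random_cdr3(rng, int(lengths[i]))
        used.add(aa)
        # log-uniform CN inside the target range, so every targeted fraction
        # receives a comparable number of injected clones
        log_cn = rng.uniform(np.log2(cn_lo), np.log2(cn_hi))
        cn = int(np.clip(round(effect.expansion_multiplier * 2.0**log_cn), cn_lo + 1, cn_hi))
        v = f"TRBV{int(rng.integers(1, config.n_v_segments + 1))}"
        jn = int(rng.integers(0, config.n_j_segments))
        j = f"TRBJ{jn // 7 + 1}-{jn % 7 + 1}"
        injected.append(_make_clonotype(rng, aa, v, j, cn, 1))
        truth.append(aa)
    clonotypes = list(rep.clonotypes) + injected
    if config.conserve_reads:
        extra = sum(c.copy_number for c in injected)
        clonotypes = _thin_reads(rng, clonotypes, injected, extra)
    return Repertoire(rep.sample_id, clonotypes, rep.group_label, rep.timepoint), truth


def _thin_reads(rng, clonotypes, injected, extra) -> list[Clonotype]:
    """Remove ``extra`` reads from non-injected clonotypes without replacement."""
    protected = {c.cdr3_aa for c in injected}
    others = [c for c in clonotypes if c.cdr3_aa not in protected]
    counts = np.array([c.copy_number for c in others])
    removable = counts - 2  # keep CN >= 2
    extra = min(extra, int(removable.sum()))
    removed = rng.multivariate_hypergeometric(removable, extra)
    out = list(injected)
    for c, r in zip(others, removed):
        if r == 0:
            out.append(c)
            continue
        new_cn = c.copy_number - int(r)
        reads = _split_reads(rng, new_cn, len(c.variants))
        variants = tuple(
            NucleotideVariant(v.nt_sequence, int(x)) for v, x in zip(c.variants, reads)
        )
        out.append(Clonotype(c.cdr3_aa, c.v_segment, c.j_segment, new_cn, variants))
    return out


def generate_cohort(config: SyntheticCohortConfig, timepoint: str = "") -> LabeledCohort:
    """Full labeled cohort: controls plus effect-injected treated animals."""
    pool = make_public_pool(config)
    repertoires: list[Repertoire] = []
    labels: list[str] = []
    truth: dict[str, list[str]] = {}
    for i in range(config.n_control):
        sid = f"control_{i + 1:02d}"
        repertoires.append(
            generate_repertoire(config, pool, sid, i, "control", timepoint)
        )
        labels.append("control")
        truth[sid] = []
    for i in range(config.n_treated):
        idx = config.n_control + i
        sid = f"immunized_{i + 1:02d}"
        rep = generate_repertoire(config, pool, sid, idx, "immunized", timepoint)
        rep, injected = inject_effect(rep, config.effect, config, idx)
        repertoires.append(rep)
        labels.append("immunized")
        truth[sid] = injected
    return LabeledCohort(repertoires, labels, truth)


def day3_like_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Early-response conditions: specific clones in the high-CN fractions 7-10."""
    cfg = SyntheticCohortConfig(
        effect=EffectConfig(target_fraction_lo=7, target_fraction_hi=10,
                            n_specific_per_animal=40),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def day7_like_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """Late-response conditions: specific clones in the low-CN fractions 1-2.

    The late effect involves many re-immigrating specific clones of low copy
    number, so the injection is larger than the early one.
    """
    cfg = SyntheticCohortConfig(
        effect=EffectConfig(target_fraction_lo=1, target_fraction_hi=2,
                            n_specific_per_animal=400),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """No injected effect: treated indistinguishable from control."""
    cfg = SyntheticCohortConfig(
        effect=EffectConfig(n_specific_per_animal=0),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
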