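"""Multi-herd pig-population simulator.

Generates pedigrees and repeated litter-size phenotypes with the structure
the evaluation pipeline assumes: several herds of unequal size, one herd
acting as an AI centre whose boars sire litters in the other herds, limited
gilt trade, two pure breeds (L, LW) plus reciprocal F1 crosses, and a
Gaussian repeatability trait

    nba = fixed part + a_sow + p_sow + l_birth_litter + e

with breeding values sampled down the pedigree (Mendelian-sampling variance
0.5 * sigma2_a * (1 - (F_s + F_d)/2)).

Everything is a deterministic function of the configuration seed.  Selection
is random (no truncation on genetic merit) so realized variance components
stay at their configured values, which the REML recovery tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, compute_inbreeding
from .varcomp import VarianceComponents

__all__ = [
    "HerdConfig",
    "FixedEffectConfig",
    "SimulationConfig",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_dataset",
    "scenario_presets",
    "PRESETS",
    "random_pedigree",
    "half_foreign_sire_scenario",
]

#: default true variance components: merged purebred+crossbred analysis scale
DEFAULT_VC = VarianceComponents(
    sigma2_a=0.970, sigma2_p=0.727, sigma2_l=0.181, sigma2_e=8.754
)

FARROW_MONTHS = (3, 9)
OTHER_BREED = {"L": "LW", "LW": "L"}


@dataclass
class HerdConfig:
    label: str
    n_founder_sows: int
    n_founder_boars: int
    #: fraction of founder females that are Landrace (rest Large White)
    frac_landrace: float = 0.5
    #: per-litter probability that a (purebred) young boar is retained
    boar_retention: float = 0.0


@dataclass
class FixedEffectConfig:
    """Small, documented, arbitrary fixed-effect magnitudes (piglets)."""

    parity_curve: tuple[float, ...] = (0.0, 0.45, 0.55, 0.5, 0.3, 0.1, -0.1, -0.3)
    season_sd: float = 0.25
    genotype: dict[str, float] = field(default_factory=lambda: {
        "L": 0.0, "LW": 0.15, "LxLW": 0.45, "LWxL": 0.45})
    herd: dict[str, float] = field(default_factory=lambda: {
        "A": 0.0, "B": -0.6, "C": 0.5})
    age_lin: float = 0.10   # per year of age deviation
    age_quad: float = -0.04
    prev_lact_lin: float = 0.004  # per day deviation
    wci_class: tuple[float, ...] = (0.0, 0.1, -0.1, -0.25)


@dataclass
class SimulationConfig:
    herds: tuple[HerdConfig, ...]
    years: int = 10
    start_year: int = 2008
    #: destination herd -> origin herd -> fraction of matings AI-sired there
    ai_sharing: dict[str, dict[str, float]] = field(default_factory=dict)
    #: origin herd -> destination herd -> probability a retained gilt moves
    gilt_trade: dict[str, dict[str, float]] = field(default_factory=dict)
    #: herd -> fraction of matings of purebred sows producing F1 litters
    crossbreeding: dict[str, float] = field(default_factory=dict)
    vc_true: VarianceComponents = field(default_factory=lambda: DEFAULT_VC)
    fixed_effects: FixedEffectConfig = field(default_factory=FixedEffectConfig)
    mean_nba: float = 16.05
    seed: int = 0
    farrow_prob: float = 0.85
    max_parity: int = 6
    gilt_retention: float = 0.30   # per potential replacement slot (2 per litter)
    retain_crossbred_gilts: bool = True
    #: founders grouped into pseudo birth litters of this size
    founder_litter_size: int = 3
    #: sow-pool cap as a multiple of the founder sow count
    pool_growth: float = 1.4
    boar_service_life: float = 3.0
    min_service_age: float = 0.9
    integer_nba: bool = False
    target_records: int | None = None

    def validate(self) -> None:
        labels = {h.label for h in self.herds}
        for dest, shares in self.ai_sharing.items():
            unknown = ({dest} | set(shares)) - labels
            if unknown:
                raise ValueError(f"ai_sharing references unknown herd(s): {sorted(unknown)}")
        for dest, shares in self.ai_sharing.items():
            tot = sum(shares.values())
            if not 0 <= tot <= 1:
                raise ValueError(f"ai_sharing fractions for '{dest}' sum to {tot}")
            for v in shares.values():
                if not 0 <= v <= 1:
                    raise ValueError("ai_sharing fractions must lie in [0, 1]")
        for origin, dests in self.gilt_trade.items():
            if not 0 <= sum(dests.values()) <= 1:
                raise ValueError(f"gilt_trade fractions from '{origin}' exceed 1")
        for h, f in self.crossbreeding.items():
            if not 0 <= f <= 1:
                raise ValueError(f"crossbreeding fraction for '{h}' not in [0, 1]")


class _Animal:
    __slots__ = ("id", "sire", "dam", "herd", "birth_year", "birth_month",
                 "sex", "breed", "birth_litter", "parity", "last_wean")

    def __init__(self, id, sire, dam, herd, birth_year, birth_month, sex,
                 breed, birth_litter):
        self.id = id
        self.sire = sire
        self.dam = dam
        self.herd = herd
        self.birth_year = birth_year
        self.birth_month = birth_month
        self.sex = sex
        self.breed = breed
        self.birth_litter = birth_litter
        self.parity = 0
        self.last_wean = None

    @property
    def birth_time(self) -> float:
        return self.birth_year + (self.birth_month - 1) / 12.0


def _pick_boar(rng, boars, breed=None):
    pool = [b for b in boars if breed is None or b.breed == breed] or boars
    if not pool:
        return None
    return pool[rng.integers(len(pool))]


def simulate_pedigree(cfg: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Run the breeding loop; returns the pedigree and raw litter records.

    The returned record table has every phenotype field except ``nba``
    (filled by :func:`simulate_phenotypes`).  Only breeding animals (founders
    and retained replacements) enter the pedigree; litter mates that leave
    the population are counted in the response only.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    animals: list[_Animal] = []
    next_id = 1
    next_litter = 1

    sow_pool: dict[str, list[_Animal]] = {h.label: [] for h in cfg.herds}
    boar_pool: dict[str, list[tuple[_Animal, float]]] = {h.label: [] for h in cfg.herds}
    sow_cap = {h.label: int(round(h.n_founder_sows * cfg.pool_growth))
               for h in cfg.herds}
    boar_cap = {h.label: max(h.n_founder_boars, 1) for h in cfg.herds}

    for hc in cfg.herds:
        # founders born over the three years before the first season so the
        # starting sow pool has staggered ages; pseudo birth litters group
        # founder females of the same herd
        group = 0
        for k in range(hc.n_founder_sows):
            if k % cfg.founder_litter_size == 0:
                group += 1
            a = _Animal(
                next_id, 0, 0, hc.label,
                cfg.start_year - 3 + int(rng.integers(3)), int(rng.integers(1, 13)),
                "F", "L" if rng.random() < hc.frac_landrace else "LW",
                f"{hc.label}F{group:03d}",
            )
            next_id += 1
            animals.append(a)
            sow_pool[hc.label].append(a)
        for _ in range(hc.n_founder_boars):
            b = _Animal(
                next_id, 0, 0, hc.label,
                cfg.start_year - 3 + int(rng.integers(3)), int(rng.integers(1, 13)),
                "M", "L" if rng.random() < hc.frac_landrace else "LW",
                f"{hc.label}B{next_id:04d}",
            )
            next_id += 1
            animals.append(b)
            boar_pool[hc.label].append((b, b.birth_time + cfg.boar_service_life + 3))

    herd_labels = [h.label for h in cfg.herds]
    records: list[dict] = []
    pending_gilts: list[tuple[float, str, _Animal]] = []
    pending_boars: list[tuple[float, str, _Animal]] = []

    for year in range(cfg.start_year, cfg.start_year + cfg.years):
        for month in FARROW_MONTHS:
            t = year + (month - 1) / 12.0
            # promote replacements that reached service age; candidates that
            # find no slot are culled and never enter the pedigree
            for due, herd, g in [x for x in pending_gilts if x[0] <= t]:
                if len(sow_pool[herd]) < sow_cap[herd]:
                    sow_pool[herd].append(g)
                    animals.append(g)
                pending_gilts.remove((due, herd, g))
            for due, herd, b in [x for x in pending_boars if x[0] <= t]:
                if len(boar_pool[herd]) < boar_cap[herd]:
                    boar_pool[herd].append((b, t + cfg.boar_service_life))
                    animals.append(b)
                    pending_boars.remove((due, herd, b))
                elif t - b.birth_time > cfg.boar_service_life:
                    # too old to stand by any longer
                    pending_boars.remove((due, herd, b))
            for herd in herd_labels:
                boar_pool[herd] = [(b, till) for b, till in boar_pool[herd] if till > t]

            for herd in herd_labels:
                active_boars = {
                    h: [b for b, _ in boar_pool[h]] for h in herd_labels}
                shares = cfg.ai_sharing.get(herd, {})
                sows = list(sow_pool[herd])
                for sow in sows:
                    age = t - sow.birth_time
                    if age < cfg.min_service_age:
                        continue
                    if sow.parity >= cfg.max_parity:
                        sow_pool[herd].remove(sow)
                        continue
                    if rng.random() > cfg.farrow_prob:
                        continue
                    # sire origin: AI share first, local otherwise
                    r = rng.random()
                    origin = herd
                    acc = 0.0
                    for o, fr in sorted(shares.items()):
                        acc += fr
                        if r < acc:
                            origin = o
                            break
                    crossbred = (
                        sow.breed in OTHER_BREED
                        and rng.random() < cfg.crossbreeding.get(herd, 0.0)
                    )
                    want = OTHER_BREED[sow.breed] if crossbred else \
                        (sow.breed if sow.breed in OTHER_BREED else None)
                    sire = _pick_boar(rng, active_boars[origin], want)
                    if sire is None:
                        sire = _pick_boar(rng, active_boars[herd], want)
                    if sire is None:
                        # emergency: promote the oldest standby candidate
                        cand = [x for x in pending_boars if x[1] == herd]
                        if cand:
                            due, _, b = cand[0]
                            pending_boars.remove((due, herd, b))
                            boar_pool[herd].append((b, t + cfg.boar_service_life))
                            animals.append(b)
                            active_boars[herd].append(b)
                            sire = b
                    if sire is None:
                        raise RuntimeError(
                            f"no boar available for herd {herd} in {year}-{month:02d}"
                        )
                    sow.parity += 1
                    litter_id = f"T{next_litter:06d}"
                    next_litter += 1
                    sow_purebred = sow.breed in OTHER_BREED
                    if sow_purebred and sire.breed != sow.breed:
                        geno = f"{sire.breed}x{sow.breed}"
                    else:
                        geno = sow.breed
                    first = sow.parity == 1
                    records.append({
                        "sow": sow.id,
                        "parity": sow.parity,
                        "year": year,
                        "month": month,
                        "genotype": sow.breed,
                        "litter_genotype": geno,
                        "litter_sire": sire.id,
                        "herd": herd,
                        "age_days": int(round(age * 365.25)),
                        "wci_days": np.nan if first else
                            float(np.round(4 + rng.gamma(2.0, 4.0), 1)),
                        "prev_lact_days": np.nan if first else
                            float(np.clip(np.round(rng.normal(26, 4)), 7, 60)),
                        "birth_litter": sow.birth_litter,
                        "litter_id": litter_id,
                    })
                    # replacement retention (random selection, capped pools);
                    # offspring of crossbred dams are never retained
                    litter_is_cross = sow_purebred and "x" in geno
                    may_keep_gilt = sow_purebred and (
                        (not litter_is_cross) or cfg.retain_crossbred_gilts)
                    if may_keep_gilt:
                        for _ in range(int(rng.binomial(2, cfg.gilt_retention))):
                            dest = herd
                            rr = rng.random()
                            acc2 = 0.0
                            for d, fr in sorted(cfg.gilt_trade.get(herd, {}).items()):
                                acc2 += fr
                                if rr < acc2:
                                    dest = d
                                    break
                            g = _Animal(next_id, sire.id, sow.id, dest, year,
                                        month, "F", geno, litter_id)
                            next_id += 1
                            pending_gilts.append((t + 1.0, dest, g))
                    hc = next(h for h in cfg.herds if h.label == herd)
                    if (sow_purebred and not litter_is_cross
                            and rng.random() < hc.boar_retention):
                        b = _Animal(next_id, sire.id, sow.id, herd, year, month,
                                    "M", geno, litter_id)
                        next_id += 1
                        pending_boars.append((t + cfg.min_service_age, herd, b))

    ped_df = pd.DataFrame({
        "animal": [a.id for a in animals],
        "sire": [a.sire for a in animals],
        "dam": [a.dam for a in animals],
        "herd": [a.herd for a in animals],
        "birth_year": [a.birth_year for a in animals],
        "sex": [a.sex for a in animals],
        "breed": [a.breed for a in animals],
    })
    ped = Pedigree.from_frame(ped_df)
    rec = pd.DataFrame(records)
    if cfg.target_records is not None and len(rec) > cfg.target_records:
        keep = np.sort(rng.choice(len(rec), size=cfg.target_records, replace=False))
        rec = rec.iloc[keep].reset_index(drop=True)
    return ped, rec


def _fixed_part(rec: pd.DataFrame, cfg: SimulationConfig,
                season_effects: dict[str, float]) -> np.ndarray:
    fe = cfg.fixed_effects
    parity = rec["parity"].to_numpy(dtype=int)
    pc = np.asarray(fe.parity_curve)
    par_eff = pc[np.minimum(parity - 1, pc.size - 1)]
    season = rec["year"].astype(str) + "-" + rec["month"].astype(str).str.zfill(2)
    sea_eff = np.array([season_effects[s] for s in season])
    gen_eff = np.array([fe.genotype.get(g, 0.0) for g in rec["genotype"]])
    herd_eff = np.array([fe.herd.get(h, 0.0) for h in rec["herd"]])
    age_dev = (rec["age_days"].to_numpy(dtype=float) - 900.0) / 365.25
    age_eff = fe.age_lin * age_dev + fe.age_quad * age_dev ** 2
    pl = rec["prev_lact_days"].to_numpy(dtype=float)
    pl_eff = np.where(np.isnan(pl), 0.0, fe.prev_lact_lin * (pl - 26.0))
    wci = rec["wci_days"].to_numpy(dtype=float)
    edges = np.array([5, 20, 40], dtype=float)
    wci_idx = np.searchsorted(edges, np.nan_to_num(wci, nan=0.0), side="left")
    wci_eff = np.where(np.isnan(wci), 0.0,
                       np.asarray(fe.wci_class)[np.minimum(wci_idx, 3)])
    return (cfg.mean_nba + par_eff + sea_eff + gen_eff + herd_eff
            + age_eff + pl_eff + wci_eff)


def simulate_phenotypes(ped: Pedigree, rec: pd.DataFrame,
                        cfg: SimulationConfig) -> pd.DataFrame:
    """Attach the simulated NBA response to the litter records."""
    rng = np.random.default_rng([cfg.seed, 1])
    vc = cfg.vc_true

    seasons = sorted(set(
        (rec["year"].astype(str) + "-" + rec["month"].astype(str).str.zfill(2))
        .tolist()))
    season_effects = {
        s: cfg.fixed_effects.season_sd * float(z)
        for s, z in zip(seasons, rng.standard_normal(len(seasons)))
    }

    F = compute_inbreeding(ped)
    a = np.zeros(ped.n)
    sd_a = np.sqrt(vc.sigma2_a)
    for i in range(ped.n):
        s, d = ped.sire_pos[i], ped.dam_pos[i]
        if s < 0 and d < 0:
            a[i] = rng.normal(0.0, sd_a) if sd_a > 0 else 0.0
            continue
        mean = 0.0
        if s >= 0 and d >= 0:
            mean = 0.5 * (a[s] + a[d])
            msv = 0.5 * vc.sigma2_a * (1 - 0.5 * (F[s] + F[d]))
        else:
            known = s if s >= 0 else d
            mean = 0.5 * a[known]
            msv = vc.sigma2_a * (0.75 - 0.25 * F[known])
        a[i] = mean + (rng.normal(0.0, np.sqrt(msv)) if msv > 0 else 0.0)

    sows = np.unique(rec["sow"].to_numpy(dtype=np.int64))
    p_eff = {int(s): (rng.normal(0.0, np.sqrt(vc.sigma2_p)) if vc.sigma2_p > 0 else 0.0)
             for s in sows}
    litters = sorted(set(rec["birth_litter"].tolist()))
    l_eff = {lt: (rng.normal(0.0, np.sqrt(vc.sigma2_l)) if vc.sigma2_l > 0 else 0.0)
             for lt in litters}

    fixed = _fixed_part(rec, cfg, season_effects)
    pos = ped.positions(rec["sow"].to_numpy())
    e = rng.normal(0.0, np.sqrt(vc.sigma2_e), size=len(rec)) \
        if vc.sigma2_e > 0 else np.zeros(len(rec))
    y = (fixed
         + a[pos]
         + np.array([p_eff[int(s)] for s in rec["sow"]])
         + np.array([l_eff[lt] for lt in rec["birth_litter"]])
         + e)
    out = rec.copy()
    if cfg.integer_nba:
        y = np.maximum(np.round(y), 0.0)
    out["nba"] = y
    out.attrs["true_breeding_values"] = pd.Series(a, index=ped.ids)
    return out


def simulate_dataset(cfg: SimulationConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree + phenotype table in one call."""
    ped, rec = simulate_pedigree(cfg)
    phen = simulate_phenotypes(ped, rec, cfg)
    return ped, phen


def _base_herds(scale: float = 1.0) -> tuple[HerdConfig, ...]:
    def sz(x):
        return max(int(round(x * scale)), 3)
    return (
        HerdConfig("A", sz(60), sz(8), frac_landrace=0.5, boar_retention=0.08),
        HerdConfig("B", sz(25), sz(12), frac_landrace=0.5, boar_retention=0.25),
        HerdConfig("C", sz(35), sz(6), frac_landrace=0.5, boar_retention=0.12),
    )


def scenario_presets(name: str, *, seed: int = 0, scale: float = 1.0,
                     years: int = 12) -> SimulationConfig:
    """Named scenario configurations.

    ``disconnected``: three isolated herds (no AI, no trade, no crosses).
    ``ai_connected``: herd B's AI centre sires ~45 % of matings in A and C,
    plus a small gilt trade out of B.
    ``ai_connected_with_crossbreds``: additionally, ~30 % of purebred-sow
    matings in A and C produce F1 litters whose gilts are retained.
    """
    base = dict(herds=_base_herds(scale), years=years, seed=seed)
    if name == "disconnected":
        return SimulationConfig(**base, retain_crossbred_gilts=False)
    if name == "ai_connected":
        return SimulationConfig(
            **base,
            ai_sharing={"A": {"B": 0.45}, "C": {"B": 0.45}},
            gilt_trade={"B": {"A": 0.10, "C": 0.10}},
            retain_crossbred_gilts=False,
        )
    if name == "ai_connected_with_crossbreds":
        return SimulationConfig(
            **base,
            ai_sharing={"A": {"B": 0.45}, "C": {"B": 0.45}},
            gilt_trade={"B": {"A": 0.10, "C": 0.10}},
            crossbreeding={"A": 0.30, "C": 0.30},
        )
    raise ValueError(
        f"unknown preset '{name}'; available: disconnected, ai_connected, "
        "ai_connected_with_crossbreds"
    )


PRESETS = ("disconnected", "ai_connected", "ai_connected_with_crossbreds")


def reml_recovery_config(seed: int, vc: VarianceComponents | None = None,
                         n_records: int = 5000) -> SimulationConfig:
    """Compact three-herd scenario sized for variance-component recovery.

    Long sow careers keep the equation count (and hence the per-iteration
    EM-REML cost) small at a fixed record count.
    """
    cfg = scenario_presets("ai_connected", seed=seed, scale=1.7, years=14)
    return replace(
        cfg,
        vc_true=vc or VarianceComponents(0.825, 1.171, 0.189, 10.324),
        max_parity=12,
        gilt_retention=0.16,
        target_records=n_records,
    )


def random_pedigree(n: int, seed: int, *, n_founders: int | None = None,
                    n_herds: int = 2,
                    missing_parent_prob: float = 0.1) -> Pedigree:
    """Random valid pedigree for oracle tests (overlapping generations)."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 5)
    rows = []
    for i in range(1, n + 1):
        if i <= n_founders:
            sire = dam = 0
        else:
            prior = np.arange(1, i)
            males = prior[prior % 2 == 0]
            females = prior[prior % 2 == 1]
            sire = int(rng.choice(males)) \
                if males.size and rng.random() > missing_parent_prob else 0
            dam = int(rng.choice(females)) \
                if females.size and rng.random() > missing_parent_prob else 0
        rows.append({
            "animal": i, "sire": sire, "dam": dam,
            "herd": f"H{i % n_herds}", "birth_year": 2000 + i // 10,
            "sex": "M" if i % 2 == 0 else "F", "breed": "L",
        })
    return Pedigree.from_frame(pd.DataFrame(rows))


def half_foreign_sire_scenario(n_progeny: int = 40) -> tuple[Pedigree, pd.Series]:
    """Designed gene-flow check: herd-A progeny, all dams local base animals,
    exactly half the sires herd-B base animals.

    The expected B gene share of the progeny group is 0.5 * 0.5 = 0.25.
    Returns the pedigree and the progeny group assignment (all "A").
    """
    rows = []
    nid = 1
    dams, sires_a, sires_b = [], [], []
    for _ in range(n_progeny):
        rows.append({"animal": nid, "sire": 0, "dam": 0, "herd": "A",
                     "birth_year": 2000, "sex": "F", "breed": "L"})
        dams.append(nid)
        nid += 1
    for _ in range(n_progeny // 4):
        rows.append({"animal": nid, "sire": 0, "dam": 0, "herd": "A",
                     "birth_year": 2000, "sex": "M", "breed": "L"})
        sires_a.append(nid)
        nid += 1
        rows.append({"animal": nid, "sire": 0, "dam": 0, "herd": "B",
                     "birth_year": 2000, "sex": "M", "breed": "L"})
        sires_b.append(nid)
        nid += 1
    progeny = []
    for k, dam in enumerate(dams):
        if k < n_progeny // 2:
            sire = sires_a[k % len(sires_a)]
        else:
            sire = sires_b[k % len(sires_b)]
        rows.append({"animal": nid, "sire": sire, "dam": dam, "herd": "A",
                     "birth_year": 2001, "sex": "F", "breed": "L"})
        progeny.append(nid)
        nid += 1
    ped = Pedigree.from_frame(pd.DataFrame(rows))
    groups = pd.Series("A", index=progeny)
    return ped, groups
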