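"""Synthetic reef-survey scenarios with known ground truth.

Generates complete, internally consistent survey datasets emulating a
three-survey (degradation, then partial recovery) monitoring programme
on eight fringing-reef sites, half of them inside a no-take protected
area:

* a pool of ~90 coral taxa whose seven raw traits are drawn around
  growth-form archetypes, so corymbose and branching taxa occupy
  extreme, hull-vertex regions of trait space while encrusting and
  massive taxa form dense near-duplicate clusters;
* line-intercept benthic transects (one 50-m tape in the first survey,
  six 10-m replicates thereafter) whose category composition follows
  per-year target covers with Dirichlet noise, total coral cover
  dropping from ~28% to ~13% and partially recovering to ~23% with a
  faster recovery at protected sites;
* belt-transect fish counts, Poisson around a linear function of site
  coral cover, with positive slopes only for large (>20 cm) non-coral
  dwellers and small (5-10 cm) coral dwellers, and non-coral-dweller
  baselines that decline year over year.

The taxon pools of the three surveys encode the headline succession
signature: all corymbose and branching taxa are present only in the
first survey (they are deleted in year 2), and year 3 adds many
near-duplicate encrusting and massive taxa, so richness rises
monotonically while occupied trait volume is V-shaped and 5-NN
redundancy falls.

All randomness flows from a single scenario seed through named
substreams (traits, benthic, fish), so any one stage can be regenerated
on its own.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reeftraits.fish import FishRecord, SIZE_CLASSES
from reeftraits.survey import (
    BENTHIC_CATEGORIES,
    CORAL_CATEGORY,
    Segment,
    TransectRecord,
)
from reeftraits.traitspace import TRAIT_NAMES

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SyntheticScenario",
    "default_trait_breaks",
    "generate_trait_pool",
    "generate_benthic_surveys",
    "generate_fish_surveys",
    "generate_scenario",
]


def default_trait_breaks() -> dict[str, tuple[float, float, float, float]]:
    """Per-trait ordinal cut points shipped with the package."""
    ref = importlib.resources.files("reeftraits.data").joinpath("trait_breaks.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return {
        row["trait"]: (row["cut1"], row["cut2"], row["cut3"], row["cut4"])
        for _, row in df.iterrows()
    }


# growth-form archetypes: raw-trait geometric means sitting at ordinal
# bin centres, designed so the eight form centroids span four
# structural trait-space directions.  Corymbose (tiny corallites, open
# colonies, high surface:volume) and branching (tall, large, low
# density) occupy two distinct hull-vertex corners whose losses are
# separable; massive and encrusting anchor the opposite corners.
_ARCHETYPES: dict[str, dict[str, float]] = {
    # form:        grw   dens  size  height cor.w space  sa:v
    "corymbose": dict(zip(TRAIT_NAMES, (115, 0.62, 17, 3.0, 0.6, 28, 5.7))),
    "branching": dict(zip(TRAIT_NAMES, (57, 0.98, 85, 85, 1.4, 14, 0.7))),
    "tabular": dict(zip(TRAIT_NAMES, (57, 0.62, 170, 8.7, 0.6, 3.2, 2.8))),
    "foliose": dict(zip(TRAIT_NAMES, (29, 0.98, 42, 8.7, 7.1, 3.2, 2.8))),
    "digitate": dict(zip(TRAIT_NAMES, (29, 1.39, 17, 8.7, 1.4, 7.1, 0.7))),
    "submassive": dict(zip(TRAIT_NAMES, (11, 1.79, 85, 42, 14, 3.2, 0.7))),
    "massive": dict(zip(TRAIT_NAMES, (11, 2.40, 170, 85, 7.1, 1.2, 0.3))),
    "encrusting": dict(zip(TRAIT_NAMES, (3.0, 1.39, 6, 3.0, 1.4, 1.2, 1.4))),
}

# within-form log-scale spread; the forms that proliferate during
# recovery (massive, encrusting, submassive) are tight clusters of
# near-duplicates, so their extra taxa densify trait space without
# expanding the occupied volume
_FORM_SD = {
    "corymbose": 0.15, "branching": 0.10, "tabular": 0.08, "foliose": 0.08,
    "digitate": 0.08, "submassive": 0.06, "massive": 0.05, "encrusting": 0.05,
}

_FORM_COUNTS = {
    "corymbose": 12, "branching": 10, "tabular": 6, "foliose": 8,
    "digitate": 6, "submassive": 10, "massive": 20, "encrusting": 18,
}

_FORM_GENERA = {
    "corymbose": ["Acropora"] * 8 + ["Stylophora"] * 2 + ["Seriatopora"] * 2,
    "branching": ["Pocillopora"] * 5 + ["Acropora"] * 3 + ["Porites"] * 2,
    "tabular": ["Acropora"] * 6,
    "foliose": ["Montipora"] * 4 + ["Echinopora"] * 2 + ["Turbinaria"] * 2,
    "digitate": ["Porites"] * 3 + ["Acropora"] * 3,
    "submassive": ["Pavona"] * 4 + ["Hydnophora"] * 3 + ["Galaxea"] * 3,
    "massive": ["Porites"] * 6 + ["Favia"] * 5 + ["Favites"] * 4 + ["Platygyra"] * 5,
    "encrusting": ["Montipora"] * 8 + ["Leptastrea"] * 5 + ["Psammocora"] * 5,
}

# how many taxa of each form occur in each survey's species pool
_YEAR_FORM_COUNTS = {
    0: {"corymbose": 12, "branching": 10, "tabular": 6, "foliose": 5,
        "digitate": 4, "submassive": 3, "massive": 6, "encrusting": 2},  # 48
    1: {"corymbose": 0, "branching": 0, "tabular": 6, "foliose": 6,
        "digitate": 6, "submassive": 8, "massive": 13, "encrusting": 11},  # 50
    2: {"corymbose": 0, "branching": 10, "tabular": 6, "foliose": 8,
        "digitate": 6, "submassive": 10, "massive": 20, "encrusting": 18},  # 78
}

# coral composition by growth form (proportions of the year's coral total)
_YEAR_FORM_PROPS = {
    0: {"corymbose": 0.29, "branching": 0.21, "tabular": 0.07, "foliose": 0.07,
        "digitate": 0.07, "submassive": 0.11, "massive": 0.14, "encrusting": 0.04},
    1: {"massive": 0.46, "encrusting": 0.23, "submassive": 0.15, "tabular": 0.05,
        "foliose": 0.06, "digitate": 0.05},
    2: {"massive": 0.39, "encrusting": 0.30, "submassive": 0.13, "branching": 0.065,
        "foliose": 0.05, "tabular": 0.035, "digitate": 0.03},
}

# non-coral benthos/substrate composition of the remainder, per year:
# bare reef peaks during the degraded survey, sand during recovery
_YEAR_SUBSTRATE_WEIGHTS = {
    0: {"rock": 0.30, "bare reef": 0.15, "sand": 0.15, "CCA": 0.10,
        "soft coral": 0.12, "macroalgae": 0.08, "zoantharian": 0.02,
        "corallimorpharian": 0.02, "sponge": 0.02, "sea anemone": 0.01,
        "other": 0.03},
    1: {"rock": 0.25, "bare reef": 0.35, "sand": 0.15, "CCA": 0.05,
        "soft coral": 0.07, "macroalgae": 0.06, "zoantharian": 0.02,
        "corallimorpharian": 0.01, "sponge": 0.02, "sea anemone": 0.01,
        "other": 0.01},
    2: {"rock": 0.22, "bare reef": 0.12, "sand": 0.30, "CCA": 0.06,
        "soft coral": 0.15, "macroalgae": 0.06, "zoantharian": 0.02,
        "corallimorpharian": 0.02, "sponge": 0.02, "sea anemone": 0.01,
        "other": 0.02},
}

_CD_TAXA = [
    "Chromis viridis", "Dascyllus reticulatus", "Dascyllus trimaculatus",
    "Gobiodon citrinus", "Paragobiodon echinocephalus",
    "Pomacentrus moluccensis", "Pomacentrus coelestis",
    "Chaetodon trifascialis", "Chaetodon octofasciatus",
    "Amphiprion clarkii", "Cirrhitichthys falco", "Labrichthys unilineatus",
]
_NCD_TAXA = [
    "Scarus ghobban", "Scarus rivulatus", "Siganus fuscescens",
    "Acanthurus nigrofuscus", "Ctenochaetus striatus",
    "Lutjanus fulviflamma", "Lethrinus nebulosus",
    "Parupeneus multifasciatus", "Thalassoma lunare",
    "Halichoeres hortulanus", "Cheilinus trilobatus", "Epinephelus merra",
    "Caesio caerulaurea", "Abudefduf vaigiensis", "Zanclus cornutus",
    "Plectorhinchus chaetodonoides", "Kyphosus cinerascens",
    "Chlorurus sordidus",
]


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study design.

    Defaults mirror the emulated monitoring programme: 8 sites (4
    protected, 4 not), surveys in 2006/2010/2018, one 50-m line
    intercept transect in the first survey then six 10-m replicates,
    belt fish transects of 150/150/60 m x 2 m at five of the sites,
    year-wise coral cover 28% -> 13% -> partial recovery with a
    protection advantage, and fish-coral coupling only for large
    non-coral dwellers and small coral dwellers.
    """

    n_sites: int = 8
    n_protected: int = 4
    years: tuple[int, ...] = (2006, 2010, 2018)
    transect_plan: tuple[tuple[float, int], ...] = ((50.0, 1), (10.0, 6), (10.0, 6))
    missing_fraction: float = 0.12
    coral_total_by_year: tuple[float, ...] = (28.0, 13.0, 23.0)
    protected_recovery_gain: float = 4.0  # +/- on year-3 coral total (pp)
    site_sd: float = 0.7  # log-scale persistent site effect on coral total
    transect_concentration: float = 400.0  # Dirichlet concentration; inf = no noise
    fish_sites: int = 8
    fish_transect_length: tuple[float, ...] = (150.0, 150.0, 60.0)
    belt_width: float = 2.0
    # standardized abundance (ind./60 m2) at the grand-mean coral cover
    ncd_totals: tuple[float, ...] = (39.5, 12.6, 9.8)
    cd_totals: tuple[float, ...] = (21.7, 14.8, 11.1)
    ncd_size_split: tuple[float, ...] = (0.15, 0.30, 0.35, 0.20)
    cd_size_split: tuple[float, ...] = (0.45, 0.35, 0.15, 0.05)
    # ind./60 m2 change per percentage point of coral cover; the coupling
    # acts on within-year cover anomalies (site cover minus the year mean),
    # so the declared yearly totals stay the expected yearly means
    slope_ncd_large: float = 0.25
    slope_cd_small: float = 0.25
    seed: int = 0

    @property
    def sites(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sites)]

    @property
    def protected_flags(self) -> dict[str, bool]:
        return {s: i < self.n_protected for i, s in enumerate(self.sites)}


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    trait_table_complete: pd.DataFrame = None
    year_pools: dict[int, list[str]] = field(default_factory=dict)
    deleted_year2: list[str] = field(default_factory=list)
    added_year3: list[str] = field(default_factory=list)
    target_coral_cover: pd.DataFrame = None  # (site, year) -> percent
    target_category_cover: pd.DataFrame = None  # (site, year) x categories
    fish_slopes: dict[tuple[str, str], float] = field(default_factory=dict)
    year_cover_reference: dict[int, float] = field(default_factory=dict)


@dataclass
class SyntheticScenario:
    """A complete generated dataset plus its ground truth."""

    config: ScenarioConfig
    trait_table: pd.DataFrame  # with masked (NaN) cells
    transects: list[TransectRecord]
    fish_records: list[FishRecord]
    cd_lookup: pd.Series
    truth: GroundTruth


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("traits", "benthic", "fish")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def generate_trait_pool(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw the taxon pool with raw traits and mask a fraction of cells.

    Returns the observable trait table (with NaN gaps) and a
    :class:`GroundTruth` holding the complete table and the per-year
    species pools.
    """
    rng = _streams(config.seed if seed is None else seed)["traits"]
    rows = []
    names = []
    forms = []
    genera = []
    counter = 0
    for form, count in _FORM_COUNTS.items():
        genus_list = _FORM_GENERA[form]
        assert len(genus_list) == count
        for i in range(count):
            counter += 1
            taxon = f"{genus_list[i]} sp{counter:02d}"
            mean = _ARCHETYPES[form]
            sd = _FORM_SD[form]
            # within-form variation is mostly allometric: one shared
            # size/rate factor per taxon plus small trait-specific
            # jitter, so congeners spread along a line in trait space
            # rather than inflating every axis independently
            shared = rng.standard_normal()
            jitter = rng.standard_normal(len(TRAIT_NAMES))
            vals = {
                t: float(mean[t] * np.exp(sd * (0.85 * shared + 0.5 * jitter[k])))
                for k, t in enumerate(TRAIT_NAMES)
            }
            rows.append(vals)
            names.append(taxon)
            forms.append(form)
            genera.append(genus_list[i])
    table = pd.DataFrame(rows, index=pd.Index(names, name="taxon"))
    table.insert(0, "growth_form", forms)
    table.insert(0, "genus", genera)

    complete = table.copy()
    n_cells = len(table) * len(TRAIT_NAMES)
    n_mask = int(round(config.missing_fraction * n_cells))
    flat = [(t, c) for t in table.index for c in TRAIT_NAMES]
    picks = rng.choice(len(flat), size=n_mask, replace=False)
    for k in picks:
        taxon, col = flat[k]
        table.loc[taxon, col] = np.nan
    # keep every trait estimable within each genus: unmask one cell if a
    # whole trait column went missing (cannot happen at 12%, but cheap)
    for col in TRAIT_NAMES:
        if table[col].isna().all():
            table.loc[table.index[0], col] = complete.loc[table.index[0], col]

    by_form = {f: [t for t, ff in zip(names, forms) if ff == f] for f in _FORM_COUNTS}
    pools = {}
    for yi, year in enumerate(config.years[:3]):
        pool = []
        for form, k in _YEAR_FORM_COUNTS[yi].items():
            pool.extend(by_form[form][:k])
        pools[year] = sorted(pool)
    deleted = sorted(set(pools[config.years[0]]) - set(pools[config.years[1]]))
    added = sorted(set(pools[config.years[2]]) - set(pools[config.years[1]]))
    truth = GroundTruth(
        trait_table_complete=complete,
        year_pools=pools,
        deleted_year2=deleted,
        added_year3=added,
    )
    return table, truth


def _site_multipliers(config: ScenarioConfig, rng) -> pd.Series:
    # mean-one lognormal, so the yearly cover targets are the expected
    # across-site means
    sd = config.site_sd
    m = np.exp(sd * rng.standard_normal(config.n_sites) - sd**2 / 2)
    return pd.Series(np.clip(m, 0.15, 3.0), index=config.sites)


def generate_benthic_surveys(
    config: ScenarioConfig,
    truth: GroundTruth,
    seed: int | None = None,
) -> list[TransectRecord]:
    """Draw line-intercept transects matching the cover trajectories.

    Per site-year, a target composition over the 12 categories (with the
    coral share split among that year's taxon pool) is realised per
    transect as a Dirichlet draw around the target, so segment lengths
    always respect the tape-length constraint and every pool taxon has
    positive cover everywhere.
    """
    rng = _streams(config.seed if seed is None else seed)["benthic"]
    site_mult = _site_multipliers(config, rng)
    protected = config.protected_flags
    years = config.years[:3]

    # year-level taxon weights within each growth form
    forms = truth.trait_table_complete["growth_form"]
    taxon_w = {
        year: pd.Series(
            rng.gamma(2.0, 1.0, size=len(truth.year_pools[year])),
            index=truth.year_pools[year],
        )
        for year in years
    }

    target_cover = {}
    target_category = {}
    transects: list[TransectRecord] = []
    for yi, year in enumerate(years):
        form_props = _YEAR_FORM_PROPS[yi]
        substrate_w = _YEAR_SUBSTRATE_WEIGHTS[yi]
        tape_length, n_reps = config.transect_plan[yi]
        for site in config.sites:
            total = config.coral_total_by_year[yi] * site_mult[site]
            if yi == 2:
                gain = config.protected_recovery_gain
                total += gain if protected[site] else -gain
            total = float(np.clip(total, 0.5, 75.0))
            target_cover[(site, year)] = total

            # per-taxon coral targets (percent)
            pool = truth.year_pools[year]
            taxon_target = {}
            for form, prop in form_props.items():
                members = [t for t in pool if forms[t] == form]
                if not members:
                    continue
                w = taxon_w[year][members]
                share = (w / w.sum()) * prop * total
                taxon_target.update(share.to_dict())
            coral_sum = sum(taxon_target.values())

            rest = 100.0 - coral_sum
            wsum = sum(substrate_w.values())
            cat_target = {
                c: rest * substrate_w.get(c, 0.0) / wsum
                for c in BENTHIC_CATEGORIES
                if c != CORAL_CATEGORY
            }
            target_category[(site, year)] = {
                **cat_target, CORAL_CATEGORY: coral_sum
            }

            labels = list(cat_target) + list(taxon_target)
            props = np.array(
                [cat_target[c] for c in cat_target]
                + [taxon_target[t] for t in taxon_target]
            ) / 100.0
            for rep in range(n_reps):
                if np.isfinite(config.transect_concentration):
                    alpha = np.maximum(props * config.transect_concentration, 1e-3)
                    realised = rng.dirichlet(alpha)
                else:
                    realised = props
                segs = []
                for lab, frac in zip(labels, realised):
                    length = float(frac * tape_length)
                    if lab in taxon_target:
                        segs.append(Segment(CORAL_CATEGORY, lab, length))
                    else:
                        segs.append(Segment(lab, None, length))
                transects.append(
                    TransectRecord(
                        site, year, protected[site], f"T{rep + 1}",
                        tape_length, segs,
                    )
                )

    truth.target_coral_cover = pd.Series(target_cover).rename("coral_cover").to_frame()
    truth.target_coral_cover.index.names = ["site", "year"]
    truth.target_category_cover = pd.DataFrame(target_category).T
    truth.target_category_cover.index.names = ["site", "year"]
    return transects


def generate_fish_surveys(
    config: ScenarioConfig,
    truth: GroundTruth,
    seed: int | None = None,
) -> tuple[list[FishRecord], pd.Series]:
    """Draw belt-transect fish counts coupled to site coral cover.

    Expected density per 60 m2 of each (dweller class, size class) cell
    is the year baseline plus ``slope x (site cover - year mean cover)``,
    floored at a small positive value; counts are Poisson at the
    transect's survey area.  Centring on the year mean keeps the
    declared yearly totals as the expected means while the slope acts on
    between-site contrasts.  Returns the records and the coral-dweller
    lookup used.
    """
    if truth.target_coral_cover is None:
        raise ValueError("generate_benthic_surveys must run first (needs cover truth)")
    rng = _streams(config.seed if seed is None else seed)["fish"]
    years = config.years[:3]
    fish_sites = config.sites[: config.fish_sites]
    # centre the coupling on the surveyed sites' mean cover so the
    # declared yearly totals remain the expected yearly means
    truth.year_cover_reference = {
        year: float(np.mean([
            truth.target_coral_cover.loc[(s, year), "coral_cover"]
            for s in fish_sites
        ]))
        for year in years
    }

    slopes = {}
    for sc in SIZE_CLASSES:
        slopes[("NCD", sc)] = config.slope_ncd_large if sc == ">20" else 0.0
        slopes[("CD", sc)] = config.slope_cd_small if sc == "5-10" else 0.0
    truth.fish_slopes = slopes

    # per-taxon relative weight and size profile, fixed for the scenario
    profiles = {}
    weights = {}
    for taxon in _CD_TAXA:
        profiles[taxon] = rng.dirichlet((4.0, 3.0, 1.5, 0.5))
        weights[taxon] = rng.gamma(2.0, 1.0)
    for taxon in _NCD_TAXA:
        profiles[taxon] = rng.dirichlet((1.5, 3.0, 3.5, 2.0))
        weights[taxon] = rng.gamma(2.0, 1.0)

    records: list[FishRecord] = []
    for yi, year in enumerate(years):
        tlen = config.fish_transect_length[yi]
        area = tlen * config.belt_width
        for site in fish_sites:
            cover = float(truth.target_coral_cover.loc[(site, year), "coral_cover"])
            dcover = cover - truth.year_cover_reference[year]
            for group, taxa, totals, split in (
                ("CD", _CD_TAXA, config.cd_totals, config.cd_size_split),
                ("NCD", _NCD_TAXA, config.ncd_totals, config.ncd_size_split),
            ):
                for ci, sc in enumerate(SIZE_CLASSES):
                    cell = totals[yi] * split[ci] + slopes[(group, sc)] * dcover
                    cell = max(cell, 0.02)
                    share = np.array([weights[t] * profiles[t][ci] for t in taxa])
                    share = share / share.sum()
                    lam = cell * share * area / 60.0
                    counts = rng.poisson(lam)
                    for taxon, cnt in zip(taxa, counts):
                        if cnt > 0:
                            records.append(
                                FishRecord(site, year, taxon, int(cnt), sc,
                                           tlen, config.belt_width)
                            )
    lookup = pd.Series(
        [True] * len(_CD_TAXA) + [False] * len(_NCD_TAXA),
        index=_CD_TAXA + _NCD_TAXA,
        name="cd_flag",
    )
    return records, lookup


def generate_scenario(config: ScenarioConfig | None = None,
                      seed: int | None = None) -> SyntheticScenario:
    """Generate a full scenario: traits, benthic transects, fish counts."""
    config = config or ScenarioConfig()
    if seed is not None:
        config = ScenarioConfig(**{**config.__dict__, "seed": seed})
    trait_table, truth = generate_trait_pool(config)
    transects = generate_benthic_surveys(config, truth)
    fish_records, lookup = generate_fish_surveys(config, truth)
    return SyntheticScenario(config, trait_table, transects, fish_records,
                             lookup, truth)
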