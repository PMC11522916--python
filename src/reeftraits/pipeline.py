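"""End-to-end orchestration: surveys in, result tables out.

One call runs the full succession analysis — benthic cover, coral
diversity with sample coverage, assemblage ordination and permutation
tests, functional trait-space metrics against the pooled reference
frame, fish abundance structure, and the mixed-model tests linking fish
to coral cover — and returns every intermediate as an inspectable
table.  ``run_pipeline`` wraps the same computation with YAML
configuration, TSV/JSON output and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from reeftraits import __version__
from reeftraits.diversity import (
    cover_to_pseudocounts,
    curve_frame,
    hill_number,
    rarefaction_curve,
    sample_coverage,
)
from reeftraits.fish import (
    FishRecord,
    partition_cd_ncd,
    read_cd_lookup,
    read_fish,
    standardize_abundance,
)
from reeftraits.mixedstats import anova_lsd, design_matrix, fit_lmm, satterthwaite_test
from reeftraits.multivariate import bray_curtis, dbrda_forward_select, pcoa, permanova
from reeftraits.survey import (
    BENTHIC_CATEGORIES,
    CORAL_CATEGORY,
    TransectRecord,
    compute_cover,
    coral_abundance_matrix,
    growth_form_cover,
    read_transects,
)
from reeftraits.synthetic import (
    ScenarioConfig,
    SyntheticScenario,
    default_trait_breaks,
    generate_scenario,
)
from reeftraits.traitspace import (
    bin_traits,
    build_trait_space,
    functional_dispersion,
    functional_redundancy_5nn,
    gower_distance,
    impute_traits,
    kde_occupancy,
    trait_volume_fraction,
)

__all__ = ["RunConfig", "analyze_surveys", "analyze_scenario", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable)."""

    seed: int = 0
    n_perm: int = 999
    pcoa_axes: int = 4
    alpha: float = 0.05
    pseudocount_resolution_cm: float = 1.0
    out_dir: str = "results"
    simulate: bool = True
    include_fish: bool = True
    include_kde: bool = False
    # input paths, used when simulate is false
    transects_path: str | None = None
    traits_path: str | None = None
    fish_path: str | None = None
    cd_lookup_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if not cfg.simulate:
            for attr in ("transects_path", "traits_path"):
                p = getattr(cfg, attr)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{attr} missing or does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so identical analyses hash identically)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _year_pseudocounts(pooled: pd.DataFrame, transects, resolution_cm: float):
    """Pooled-year coral pseudo-counts from percent cover and tape length."""
    tape_by_year = {}
    for rec in transects:
        tape_by_year[rec.year] = tape_by_year.get(rec.year, 0.0) + rec.transect_length
    counts = {}
    for year in pooled.index:
        row = pooled.loc[year]
        present = row[row > 0]
        counts[year] = pd.Series(
            cover_to_pseudocounts(present.to_numpy(), tape_by_year[year],
                                  resolution_cm),
            index=present.index,
        )
    return counts


def analyze_surveys(
    transects: Sequence[TransectRecord],
    trait_table: pd.DataFrame,
    fish_records: Sequence[FishRecord] | None = None,
    cd_lookup: pd.Series | None = None,
    *,
    seed: int,
    n_perm: int = 999,
    pcoa_axes: int = 4,
    alpha: float = 0.05,
    pseudocount_resolution_cm: float = 1.0,
    include_kde: bool = False,
    trait_breaks: dict | None = None,
) -> dict:
    """Run every analysis stage and return a dict of result tables.

    ``trait_table`` needs columns genus, growth_form and the seven raw
    traits (gaps allowed; they are imputed).  Fish stages are skipped
    when ``fish_records`` is None.
    """
    results: dict = {}

    # --- benthic cover ------------------------------------------------
    cover = compute_cover(transects, group_by=("site", "year"))
    results["cover"] = cover
    coral_by_year = cover[CORAL_CATEGORY].groupby(level="year").mean()
    results["coral_cover_by_year"] = coral_by_year

    site_year = coral_abundance_matrix(transects, level="site-year")
    pooled = coral_abundance_matrix(transects, level="pooled-year")
    results["abundance_site_year"] = site_year
    results["abundance_pooled_year"] = pooled

    traits_imputed = impute_traits(trait_table)
    results["trait_table_imputed"] = traits_imputed
    results["growth_form_cover"] = growth_form_cover(pooled, traits_imputed)

    # --- coral cover mixed model (protection x year, site random) -----
    frame = pd.DataFrame(
        {
            "cover": cover[CORAL_CATEGORY].to_numpy(),
            "site": cover.index.get_level_values("site"),
            "year": cover.index.get_level_values("year").astype(str),
        }
    )
    frame["protected"] = [
        cover.attrs["protected"][key] for key in cover.index
    ]
    X = design_matrix(
        frame,
        categorical=("protected", "year"),
        interactions=(("protected", "year"),),
    )
    fit = fit_lmm(frame["cover"], X, {"site": frame["site"].to_numpy()})
    results["cover_lmm"] = fit.summary()
    results["cover_lmm_fit"] = fit

    # --- diversity ----------------------------------------------------
    counts_by_year = _year_pseudocounts(pooled, transects,
                                        pseudocount_resolution_cm)
    div_rows = []
    curves = []
    for year, counts in counts_by_year.items():
        p = counts / counts.sum()
        n = int(counts.sum())
        div_rows.append(
            {
                "year": year,
                "richness": int((counts > 0).sum()),
                "hill_q0": hill_number(p, 0),
                "hill_q1": hill_number(p, 1),
                "hill_q2": hill_number(p, 2),
                "coverage": sample_coverage(counts.to_numpy()),
                "n_pseudocounts": n,
            }
        )
        grid = np.unique(np.concatenate(
            [np.linspace(1, 2 * n, 12).astype(int), [n]]))
        for q in (0, 1, 2):
            curves.append(curve_frame(
                rarefaction_curve(counts.to_numpy(), q, grid), unit=str(year)))
    results["diversity"] = pd.DataFrame(div_rows).set_index("year")
    results["rarefaction"] = pd.concat(curves, ignore_index=True)

    # --- multivariate composition ------------------------------------
    d_coral = bray_curtis(site_year)
    design = pd.DataFrame(
        {
            "year": site_year.index.get_level_values("year").astype(str),
            "protected": [
                str(site_year.attrs["protected"][key]) for key in site_year.index
            ],
        }
    )
    results["pcoa"] = pcoa(d_coral, n_axes=2)
    results["permanova"] = permanova(
        d_coral, design, ("year", "protected", "year:protected"),
        n_perm=n_perm, seed=seed,
    )
    candidates = cover[list(BENTHIC_CATEGORIES)].copy()
    candidates.columns = [c.replace(" ", "_") for c in candidates.columns]
    results["dbrda"] = dbrda_forward_select(d_coral, candidates)

    # --- trait space ---------------------------------------------------
    breaks = trait_breaks or default_trait_breaks()
    observed = [t for t in pooled.columns if pooled[t].sum() > 0]
    ordinal = bin_traits(traits_imputed.loc[observed], breaks)
    results["trait_ordinal"] = ordinal
    gower = gower_distance(ordinal)
    space = build_trait_space(gower, n_axes=pcoa_axes)
    results["trait_space"] = space

    metric_rows = []
    kde_maps = {}
    for year in pooled.index:
        row = pooled.loc[year]
        present = [t for t in observed if row[t] > 0]
        vol = trait_volume_fraction(space, present)
        metric_rows.append(
            {
                "year": year,
                "n_taxa": len(present),
                "volume_fraction": vol.fraction,
                "volume_degenerate": vol.degenerate,
                "redundancy_5nn": functional_redundancy_5nn(space, present),
                "dispersion": functional_dispersion(space, row[present]),
            }
        )
        if include_kde:
            for pair in ((1, 2), (3, 4)):
                kde_maps[(year, pair)] = kde_occupancy(space, present, pair)
    results["trait_metrics"] = pd.DataFrame(metric_rows).set_index("year")
    if include_kde:
        results["kde_maps"] = kde_maps

    if fish_records is None:
        return results

    # --- fish ----------------------------------------------------------
    if cd_lookup is None:
        raise ValueError("fish records given without a coral-dweller lookup")
    by_taxon = standardize_abundance(fish_records, by="taxon")
    by_ts = standardize_abundance(fish_records, by="taxon-size")
    cd_tab, ncd_tab = partition_cd_ncd(by_ts, cd_lookup)
    totals = pd.DataFrame(
        {
            "total": by_taxon.sum(axis=1),
            "CD": cd_tab.sum(axis=1),
            "NCD": ncd_tab.sum(axis=1),
        }
    )
    for sc in ("<5", "5-10", "10-20", ">20"):
        cols = [c for c in by_ts.columns if c[1] == sc]
        totals[f"size_{sc}"] = by_ts[cols].sum(axis=1)
        totals[f"CD_{sc}"] = cd_tab[[c for c in cd_tab.columns if c[1] == sc]].sum(axis=1)
        totals[f"NCD_{sc}"] = ncd_tab[[c for c in ncd_tab.columns if c[1] == sc]].sum(axis=1)
    results["fish_abundance"] = totals
    results["fish_abundance_by_year"] = totals.groupby(level="year").mean()

    years = totals.index.get_level_values("year")
    results["fish_anova"] = anova_lsd(totals["total"], years.astype(str),
                                      alpha=alpha)

    d_fish = bray_curtis(by_taxon)
    fish_design = pd.DataFrame(
        {
            "year": years.astype(str),
            "protected": [
                str(cover.attrs["protected"].get(key, False))
                for key in totals.index
            ],
        }
    )
    results["fish_permanova"] = permanova(
        d_fish, fish_design, ("year", "protected", "year:protected"),
        n_perm=n_perm, seed=seed + 1,
    )
    cd_ncd_cols = pd.DataFrame({"CD": totals["CD"], "NCD": totals["NCD"]})
    results["fish_dbrda"] = dbrda_forward_select(d_fish, cd_ncd_cols)

    # --- fish ~ coral cover mixed models -------------------------------
    cover_lookup = cover[CORAL_CATEGORY]
    frame = pd.DataFrame(
        {
            "large_fish": totals["size_>20"].to_numpy(),
            "cd_small": totals["CD_5-10"].to_numpy(),
            "cover": [cover_lookup.loc[key] for key in totals.index],
            "site": totals.index.get_level_values("site"),
            "year": totals.index.get_level_values("year").astype(str),
        }
    )
    groups = {"site": frame["site"].to_numpy(), "year": frame["year"].to_numpy()}
    lmm_rows = []
    for resp in ("large_fish", "cd_small"):
        Xf = design_matrix(frame, numeric=("cover",))
        f = fit_lmm(frame[resp], Xf, groups)
        t, df, p = satterthwaite_test(f, "cover")
        lmm_rows.append(
            {
                "response": resp,
                "slope": f.params["cover"],
                "se": f.bse["cover"],
                "t": t,
                "df": df,
                "p": p,
            }
        )
    results["fish_lmm"] = pd.DataFrame(lmm_rows).set_index("response")
    return results


def analyze_scenario(scenario: SyntheticScenario, *, n_perm: int = 999,
                     include_kde: bool = False) -> dict:
    """Run the full analysis on a generated scenario."""
    return analyze_surveys(
        scenario.transects,
        scenario.trait_table,
        scenario.fish_records,
        scenario.cd_lookup,
        seed=scenario.config.seed,
        n_perm=n_perm,
        include_kde=include_kde,
    )


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#generated-by reeftraits {header}\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline per config, write result tables and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[dict] = []

    if config.simulate:
        scen_cfg = ScenarioConfig(seed=config.seed)
        scenario = generate_scenario(scen_cfg)
        transects = scenario.transects
        trait_table = scenario.trait_table
        fish_records = scenario.fish_records if config.include_fish else None
        cd_lookup = scenario.cd_lookup
    else:
        transects = read_transects(config.transects_path)
        trait_table = pd.read_csv(config.traits_path, sep="\t", index_col=0)
        fish_records = None
        cd_lookup = None
        if config.include_fish and config.fish_path:
            fish_records = read_fish(config.fish_path)
            cd_lookup = read_cd_lookup(config.cd_lookup_path)
    stage_log.append({"stage": "inputs", "elapsed_s": round(time.time() - t0, 3),
                      "n_transects": len(transects)})

    results = analyze_surveys(
        transects, trait_table, fish_records, cd_lookup,
        seed=config.seed,
        n_perm=config.n_perm,
        pcoa_axes=config.pcoa_axes,
        alpha=config.alpha,
        pseudocount_resolution_cm=config.pseudocount_resolution_cm,
        include_kde=config.include_kde,
    )
    stage_log.append({"stage": "analysis",
                      "elapsed_s": round(time.time() - t0, 3)})

    header = f"seed={config.seed} config={config.config_hash()}"
    written = []
    table_keys = [
        "cover", "growth_form_cover", "diversity", "rarefaction",
        "permanova", "trait_metrics", "cover_lmm",
    ]
    if fish_records is not None:
        table_keys += ["fish_abundance", "fish_abundance_by_year",
                       "fish_permanova", "fish_lmm"]
    for key in table_keys:
        path = out / f"{key}.tsv"
        _write_tsv(results[key], path, header)
        written.append(path.name)

    _write_tsv(results["pcoa"].coordinates, out / "pcoa_scores.tsv", header)
    written.append("pcoa_scores.tsv")
    _write_tsv(results["dbrda"].steps, out / "dbrda_steps.tsv", header)
    written.append("dbrda_steps.tsv")
    if config.include_kde:
        for (year, pair), kmap in results["kde_maps"].items():
            name = f"kde_{year}_axes{pair[0]}{pair[1]}.tsv"
            _write_tsv(pd.DataFrame(kmap.density, index=kmap.y, columns=kmap.x),
                       out / name, header)
            written.append(name)

    manifest = {
        "package": "reeftraits",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "outputs": sorted(written),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["stage_log"] = stage_log
    return results
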