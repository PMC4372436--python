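"""Config-driven end-to-end assessment run and the conservation report.

``run_assessment`` reproduces the full analysis surface from a tree and a
set of CSV inputs: the per-subregion alpha-diversity table, six
dissimilarity matrices (species/family/RE Bray-Curtis, Dpw, Dnn,
UniFrac), NMDS ordinations of each (2D and 3D, with and without excluded
sites), a Mantel/RELATE correlation matrix over all dissimilarity pairs
with Bonferroni adjustment, diversity-attribute Spearman correlations
(both site subsets), the species accumulation curve, the log-log PD~SR
regression, and a conservation-priority report.  All randomness derives
from one master seed so a repeated run is byte-identical.

The conservation report operationalizes two priority perspectives: raw
diversity (high PD) and distinctiveness (mean UniFrac distance to other
sites).  A site is flagged priority when its PD rank is in the top third
while less than ``pa_threshold`` percent of its remnant rainforest is in
protected areas; the default threshold of 17% echoes the CBD Aichi
protected-area target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import __version__
from .alpha import alpha_table, derive_seed, records_to_frame
from .beta import bray_curtis, dnn, dpw, unifrac
from .community import (
    SubregionAttributes,
    accumulation_curve,
    load_attributes,
    load_community,
    load_taxonomy,
)
from .ordination import nmds
from .stats import bonferroni, correlation_suite, loglog_pd_sr, mantel_relate
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_assessment", "conservation_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    tree: str | Path
    communities: str | Path
    taxonomy: str | Path | None = None
    attributes: str | Path | None = None
    re_incidence: str | Path | None = None
    n_rand: int = 999
    n_perm: int = 999
    nmds_dims: tuple[int, ...] = (2, 3)
    exclude_sites: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str | Path = "phylodiv_out"

    def __post_init__(self) -> None:
        if self.n_rand < 99 or self.n_perm < 99:
            raise ValueError("n_rand and n_perm must be >= 99")
        for k in self.nmds_dims:
            if k not in (2, 3):
                raise ValueError("nmds_dims entries must be 2 or 3")
        for path in (self.tree, self.communities, self.taxonomy,
                     self.attributes, self.re_incidence):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _write_distance(dm: DistanceMatrix, outdir: Path, name: str) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "site"
    df.to_csv(outdir / f"dist_{name}.csv", float_format="%.10g")
    rows = []
    ids = list(dm.ids)
    for i in range(1, len(ids)):
        for j in range(i):
            rows.append({"site_a": ids[i], "site_b": ids[j],
                         "distance": dm.data[i, j]})
    pd.DataFrame(rows).to_csv(
        outdir / f"dist_{name}_flat.csv", index=False, float_format="%.10g"
    )


def _subset_dm(dm: DistanceMatrix, drop: set[str]) -> DistanceMatrix:
    keep = [i for i in dm.ids if i not in drop]
    return dm.filter(keep)


def conservation_report(
    alpha_frame: pd.DataFrame,
    attrs: pd.DataFrame,
    pa_threshold: float = 17.0,
    unifrac_dm: DistanceMatrix | None = None,
) -> tuple[pd.DataFrame, float]:
    """Rank sites for conservation priority; also return regional coverage.

    Returns ``(table, weighted_pa_coverage)`` where the coverage is the
    remnant-area-weighted mean of per-site protected percentages,
    Sum(pct_pa * rem_rf_ha) / Sum(rem_rf_ha) -- the share of the region's
    remaining rainforest that sits in protected areas.  The table has one
    row per site: PD, PD rank (1 = most diverse), pct_pa, a
    distinctiveness score (mean UniFrac distance to all other sites, when
    a matrix is supplied) and the priority flag (PD rank in the top third
    and pct_pa below the threshold).
    """
    sites = [s for s in alpha_frame.index if s != "Total" and s in attrs.index]
    pd_vals = alpha_frame.loc[sites, "pd"].astype(float)
    rank = pd_vals.rank(ascending=False, method="min").astype(int)
    pct_pa = attrs.loc[sites, "pct_pa"].astype(float)
    rem = attrs.loc[sites, "rem_rf_ha"].astype(float)

    ok = pct_pa.notna() & rem.notna()
    coverage = float((pct_pa[ok] * rem[ok]).sum() / rem[ok].sum())

    top_third = rank <= int(np.ceil(len(sites) / 3))
    priority = top_third & (pct_pa < pa_threshold)

    table = pd.DataFrame(
        {
            "pd": pd_vals,
            "pd_rank": rank,
            "pct_pa": pct_pa,
            "priority": priority.fillna(False).astype(bool),
        },
        index=pd.Index(sites, name="site"),
    )
    if unifrac_dm is not None:
        dist = pd.Series(np.nan, index=table.index)
        ids = [i for i in unifrac_dm.ids if i in set(sites)]
        sub = unifrac_dm.filter(ids)
        n = len(ids)
        if n > 1:
            dist.loc[ids] = sub.data.sum(axis=1) / (n - 1)
        table["distinctiveness"] = dist
    table = table.sort_values(
        ["priority", "pd_rank"], ascending=[False, True], kind="stable"
    )
    return table, coverage


def run_assessment(cfg: RunConfig) -> dict:
    """Run every analysis stage and write the output bundle.

    Returns a manifest dict (also written as ``manifest.json``).  On a
    stage failure a ``FAILED`` marker naming the stage is left in the
    output directory and a :class:`StageError` is raised; outputs of
    completed stages are retained.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": [],
    }
    stage_name = "setup"

    def stage(name: str):
        nonlocal stage_name
        stage_name = name
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        tree = PhyloTree.from_file(cfg.tree)
        cm = load_community(cfg.communities)
        tax = load_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
        attrs = (
            load_attributes(cfg.attributes) if cfg.attributes else None
        )
        re_cm = load_community(cfg.re_incidence) if cfg.re_incidence else None

        stage("alpha")
        t0 = time.perf_counter()
        records = alpha_table(
            tree, cm, tax, n_rand=cfg.n_rand, seed=derive_seed(cfg.seed, "alpha")
        )
        frame = records_to_frame(records)
        frame.to_csv(outdir / "alpha.csv", float_format="%.10g")
        with open(outdir / "alpha_meta.json", "w") as fh:
            json.dump(
                {"n_rand": cfg.n_rand, "seed": cfg.seed,
                 "sign_convention": "positive z = phylogenetic evenness"},
                fh, indent=2, sort_keys=True,
            )
        logger.info("alpha done in %.1fs", time.perf_counter() - t0)

        stage("beta")
        dist = tree.patristic_distances()
        matrices: dict[str, DistanceMatrix] = {
            "bc_species": bray_curtis(cm.table, binary=True),
            "dpw": dpw(dist, cm),
            "dnn": dnn(dist, cm),
            "unifrac": unifrac(tree, cm),
        }
        if tax is not None:
            from .community import family_rollup

            _, fam_abund = family_rollup(cm, tax)
            matrices["bc_family"] = bray_curtis(fam_abund, binary=False)
        if re_cm is not None:
            matrices["bc_re"] = bray_curtis(re_cm.table, binary=True)
        for name, dm in matrices.items():
            _write_distance(dm, outdir, name)

        stage("nmds")
        exclude = set(map(str, cfg.exclude_sites))
        stress_rows = []
        for name, dm in matrices.items():
            for subset_name, drop in (("all", set()), ("excluded", exclude)):
                if subset_name == "excluded" and not exclude:
                    continue
                sub = _subset_dm(dm, drop)
                for k in cfg.nmds_dims:
                    if sub.shape[0] < k + 2:
                        continue
                    res = nmds(
                        sub, k=k,
                        seed=derive_seed(cfg.seed, "nmds", name, subset_name, str(k)),
                    )
                    res.as_frame().to_csv(
                        outdir / f"nmds_{name}_{subset_name}_{k}d.csv",
                        float_format="%.10g",
                    )
                    stress_rows.append(
                        {"matrix": name, "subset": subset_name, "k": k,
                         "stress": res.stress, "converged": res.converged,
                         "best_start_seed": res.best_start_seed}
                    )
        with open(outdir / "nmds_stress.json", "w") as fh:
            json.dump(stress_rows, fh, indent=2, sort_keys=True)

        stage("mantel")
        names = sorted(matrices)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = mantel_relate(
                    matrices[a], matrices[b], n_perm=cfg.n_perm,
                    seed=derive_seed(cfg.seed, "mantel", a, b),
                )
                rows.append({"matrix_a": a, "matrix_b": b, "rho": res.rho,
                             "p": res.p, "n_perm": res.n_perm})
        mantel_df = pd.DataFrame(rows)
        if len(mantel_df):
            mantel_df["p_adj"] = bonferroni(mantel_df["p"], m=len(mantel_df))
        mantel_df.to_csv(outdir / "mantel.csv", index=False, float_format="%.10g")

        stage("correlations")
        if attrs is not None:
            suite = correlation_suite(frame, attrs.table, exclude=exclude)
            suite.to_csv(outdir / "correlations.csv", index=False,
                         float_format="%.10g")

        stage("accumulation")
        accumulation_curve(cm).to_csv(outdir / "accumulation.csv", index=False)

        stage("regression")
        try:
            reg = loglog_pd_sr([r for r in records if r.site != "Total"])
            reg_payload = dataclasses.asdict(reg)
        except ValueError as exc:  # e.g. all sites share one richness
            reg_payload = {"degenerate": str(exc)}
        with open(outdir / "regression.json", "w") as fh:
            json.dump(reg_payload, fh, indent=2, sort_keys=True)

        stage("conservation")
        if attrs is not None:
            report, coverage = conservation_report(
                frame, attrs.table, unifrac_dm=matrices["unifrac"]
            )
            report.to_csv(outdir / "conservation.csv", float_format="%.10g")
            with open(outdir / "conservation_summary.json", "w") as fh:
                json.dump({"weighted_pa_coverage_pct": coverage}, fh,
                          indent=2, sort_keys=True)

        stage("manifest")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage_name}\n{exc}\n")
        raise StageError(f"stage {stage_name!r} failed: {exc}") from exc
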