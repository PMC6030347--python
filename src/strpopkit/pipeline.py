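"""One-command analysis flow: frequencies -> forensic panel + HWE -> LD ->
distances -> NJ tree -> MDS.

Every stage writes plain delimited text (plus one JSON summary) before the
next stage starts, so partial results survive a failure and each output is
independently diffable.  All randomized stages draw from independent
streams derived from the master seed and the stage name: adding or
removing a stage never shifts another stage's results.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .exact_tests import (
    bonferroni_threshold,
    format_two_sig,
    hwe_exact_test,
    ld_test_matrix,
)
from .forensic import cumulative_panel, locus_summary
from .io import (
    write_allele_frequency_table,
    write_distance_matrix,
    write_newick,
)
from .model import DistanceMatrix, GenotypeTable, stable_seed
from .distances import distance_table, fst_permutation_pvalue, wc_theta
from .tree_mds import classical_mds, cluster_report, neighbor_joining

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis"]

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Knobs for a full pipeline run."""

    out_dir: str | Path = "strpopkit_out"
    he_mode: str = "unbiased"          # biased | unbiased
    mp_mode: str = "observed"          # observed | hwe_expected
    hwe_method: str = "auto"           # auto | enumerate | mc | mcmc
    hwe_reps: int = 100_000
    hwe_burnin: int = 10_000
    #: pipeline throughput cap on exhaustive enumeration; above this the
    #: Monte-Carlo sampler takes over (library default is 10^6)
    hwe_enum_limit: int = 20_000
    ld_reps: int = 2000
    fst_permutations: int = 1000
    alpha: float = 0.05
    mds_dimensions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ReportBundle:
    """Paths and in-memory results of a completed (or partial) run."""

    out_dir: Path
    frequency_tables: dict[str, Path] = field(default_factory=dict)
    forensic_table: Path | None = None
    panel_summary: dict | None = None
    ld_matrix: Path | None = None
    fst_table: Path | None = None
    distance_matrices: dict[str, Path] = field(default_factory=dict)
    newick: Path | None = None
    mds_coordinates: Path | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    log_file: Path | None = None


def _stage_seed(master: int, stage: str) -> int:
    return int(np.random.SeedSequence(
        [master, stable_seed(stage)]).generate_state(1)[0]) & 0x7FFFFFFF


def run_full_analysis(tables: Sequence[GenotypeTable],
                      config: AnalysisConfig | None = None,
                      reference_spectra: dict[str, dict] | None = None,
                      ) -> ReportBundle:
    """Run every applicable stage on one or more genotype tables.

    ``reference_spectra`` optionally maps population name -> {locus ->
    AlleleFrequencySpectrum} for frequency-only reference populations
    (they join the distance/tree/MDS stages but not the forensic panel).
    Stages whose inputs are missing (e.g. MDS with < 3 populations) are
    skipped with a logged reason.
    """
    cfg = config or AnalysisConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    run_log: list[str] = [f"strpopkit {__version__}",
                          f"seed {cfg.seed}",
                          f"config {cfg.__dict__}"]
    if not tables:
        raise ValueError("need at least one genotype table")
    primary = tables[0]

    # stage 1: allele frequencies -----------------------------------------
    for t in tables:
        specs = [t.allele_spectrum(l) for l in t.loci]
        path = out / f"freqs_{t.population_id}.csv"
        write_allele_frequency_table(specs, path, precision=None)
        bundle.frequency_tables[t.population_id] = path
    run_log.append(f"frequencies written for {len(tables)} population(s)")

    # stage 2: forensic panel + HWE ----------------------------------------
    hwe_seed = _stage_seed(cfg.seed, "hwe")
    rows = []
    stats = []
    for locus in primary.loci:
        s = locus_summary(primary, locus, he_mode=cfg.he_mode,
                          mp_mode=cfg.mp_mode)
        res = hwe_exact_test(primary.genotype_counts(locus),
                             method=cfg.hwe_method, reps=cfg.hwe_reps,
                             burnin=cfg.hwe_burnin,
                             enumeration_limit=cfg.hwe_enum_limit,
                             seed=stable_seed(hwe_seed, locus))
        s.hwe_p = res.p_value
        stats.append(s)
        r = s.rounded()
        r["hwe_method"] = res.method
        rows.append(r)
    panel = cumulative_panel(stats)
    forensic_path = out / "forensic_parameters.csv"
    import pandas as pd

    pd.DataFrame(rows).to_csv(forensic_path, index=False)
    bundle.forensic_table = forensic_path
    bundle.panel_summary = {
        "CPD": panel.CPD,
        "CPE": panel.CPE,
        "cmp_product": panel.cmp_product,
        "cpe_complement": panel.cpe_complement,
        "loci_used": panel.loci_used,
        "he_mode": cfg.he_mode,
        "mp_mode": cfg.mp_mode,
        "seed": cfg.seed,
    }
    with open(out / "panel_summary.json", "w") as fh:
        json.dump(bundle.panel_summary, fh, indent=1)
    run_log.append(f"forensic panel over {len(stats)} loci: "
                   f"CPE={panel.CPE:.10f} CPD complement="
                   f"{panel.cmp_product:.3e}")

    # stage 3: pairwise LD -------------------------------------------------
    if len(primary.loci) >= 2:
        ld = ld_test_matrix(primary, reps=cfg.ld_reps, alpha=cfg.alpha,
                            seed=_stage_seed(cfg.seed, "ld"))
        ld_path = out / "ld_pvalues.csv"
        with open(ld_path, "w") as fh:
            fh.write("locusA,locusB,G,p_value\n")
            for (la, lb), res in sorted(ld.results.items()):
                fh.write(f"{la},{lb},{res.statistic:.6f},"
                         f"{res.p_value:.6g}\n")
        bundle.ld_matrix = ld_path
        run_log.append(
            f"LD: {ld.n_pairs} pairs, Bonferroni alpha "
            f"{format_two_sig(ld.bonferroni_alpha)}, "
            f"{len(ld.significant_pairs)} significant")
    else:
        bundle.skipped["ld"] = "fewer than 2 loci"

    # stage 4: interpopulation distances ------------------------------------
    pops: list[tuple[str, object]] = [(t.population_id, t) for t in tables]
    if reference_spectra:
        pops += list(reference_spectra.items())
    if len(pops) >= 2:
        fst_seed = _stage_seed(cfg.seed, "fst")
        if len(tables) >= 2:
            per_locus = wc_theta([tables[0], tables[1]], per_locus=True)
            fst_path = out / "fst_per_locus.csv"
            with open(fst_path, "w") as fh:
                fh.write("locus,theta,p_value\n")
                for r in per_locus:
                    pr = fst_permutation_pvalue(
                        tables[0], tables[1], loci=[r.locus],
                        reps=cfg.fst_permutations,
                        seed=stable_seed(fst_seed, r.locus))
                    fh.write(f"{r.locus},{r.theta:.6f},{pr.p_value:.6g}\n")
            bundle.fst_table = fst_path
            run_log.append("per-locus Fst with permutation p-values written")
        for metric in ("da", "fst"):
            dm = distance_table(pops, metric=metric)
            path = out / f"distance_{metric}.csv"
            write_distance_matrix(dm, path)
            bundle.distance_matrices[metric] = path
        run_log.append(f"pairwise distance matrices over {len(pops)} "
                       "populations written")
    else:
        bundle.skipped["distances"] = "fewer than 2 populations"

    # stage 5: NJ tree ------------------------------------------------------
    if len(pops) >= 3:
        dm = distance_table(pops, metric="da")
        tree = neighbor_joining(dm.floored())
        tree_path = out / "nj_da.nwk"
        write_newick(tree, tree_path)
        bundle.newick = tree_path
        run_log.append("NJ tree written")
    else:
        bundle.skipped["nj"] = "fewer than 3 populations"

    # stage 6: MDS ----------------------------------------------------------
    if len(pops) >= 3:
        dm = distance_table(pops, metric="fst")
        emb = classical_mds(dm.floored(), k=cfg.mds_dimensions)
        mds_path = out / "mds_coordinates.csv"
        with open(mds_path, "w") as fh:
            dims = ",".join(f"dim{i+1}" for i in range(emb.k))
            fh.write(f"population,{dims}\n")
            for lab in emb.labels:
                xy = ",".join(f"{v:.8f}" for v in emb.coords_of(lab))
                fh.write(f"{lab},{xy}\n")
        with open(out / "mds_eigenvalues.csv", "w") as fh:
            fh.write("rank,eigenvalue\n")
            for i, ev in enumerate(emb.eigenvalues, 1):
                fh.write(f"{i},{ev:.10g}\n")
        bundle.mds_coordinates = mds_path
        run_log.append(cluster_report(emb))
    else:
        bundle.skipped["mds"] = "fewer than 3 populations"

    for stage, reason in bundle.skipped.items():
        run_log.append(f"skipped {stage}: {reason}")
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(run_log) + "\n", encoding="utf-8")
    bundle.log_file = log_path
    return bundle
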