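"""End-to-end orchestration: simulate/load -> annotate -> stats -> SFS -> DFE -> alpha."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd
import yaml

import dfemk
from dfemk import annotate as ann
from dfemk import stats as pg_stats
from dfemk import alpha as alpha_mod
from dfemk.sfs import build_grouped_folded_sfs
from dfemk.simulate import SimulationConfig, generate_locus_set, read_locus_set

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input mode: ``input_dir`` (FASTA + feature table on disk) or
    ``simulation`` (a :class:`SimulationConfig` mapping).
    """

    out_dir: str
    seed: int
    input_dir: Optional[str] = None
    simulation: Optional[dict] = None
    neutral_reference: str = "4fold"
    outgroup: str = "close"
    cpg_filter: Optional[bool] = None
    bootstrap_reps: int = 200
    fixed_n: int = 20
    grid_two_n1: int = 100
    classes: tuple = ("0fold", "2fold", "4fold", "intron")

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("exactly one of input_dir / simulation required")
        if self.neutral_reference not in ("4fold", "intron"):
            raise ValueError("neutral_reference must be '4fold' or 'intron'")
        if self.outgroup not in ("close", "far"):
            raise ValueError("outgroup must be 'close' or 'far'")
        if self.bootstrap_reps > 0 and self.seed is None:
            raise ValueError("seed is mandatory when bootstrapping")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "classes" in data:
            data["classes"] = tuple(data["classes"])
        return cls(**data)


def validate_inputs(loci) -> Dict[str, List[str]]:
    """Consistency checks on raw loci; returns {'errors': [...], 'warnings': [...]}."""
    errors: List[str] = []
    warnings_: List[str] = []
    for locus in loci:
        length = len(locus.reference)
        if len(locus.alleles) % 2 != 0:
            errors.append(f"{locus.locus_id}: odd number of sample alleles")
        stems: Dict[str, int] = {}
        for name in locus.allele_names:
            stems[name.rsplit("_", 1)[0]] = stems.get(name.rsplit("_", 1)[0], 0) + 1
        for stem, cnt in stems.items():
            if cnt != 2:
                errors.append(
                    f"{locus.locus_id}: individual {stem} has {cnt} alleles (need 2)"
                )
        for seq in list(locus.alleles) + [locus.outgroup_close, locus.outgroup_far]:
            if len(seq) != length:
                errors.append(f"{locus.locus_id}: unequal aligned lengths")
                break
        cds_len = sum(f[1] - f[0] for f in locus.features if f[2] == "CDS")
        if cds_len % 3 != 0:
            errors.append(
                f"{locus.locus_id}: total CDS length {cds_len} not divisible by 3"
            )
        spans = sorted((f[0], f[1]) for f in locus.features)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                errors.append(f"{locus.locus_id}: overlapping features")
        if any(f[1] > length or f[0] < 0 for f in locus.features):
            errors.append(f"{locus.locus_id}: feature outside sequence")
        if not locus.features:
            warnings_.append(f"{locus.locus_id}: no features")
    return {"errors": errors, "warnings": warnings_}


def _stage(log, name, msg, *args):
    log.info("[%s] " + msg, name, *args)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the full analysis and write TSV/JSON reports into ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log = logging.getLogger("dfemk.pipeline.run")
    log.setLevel(logging.INFO)
    log.addHandler(handler)
    try:
        _stage(log, "setup", "dfemk %s seed=%d", dfemk.__version__, config.seed)

        if config.simulation is not None:
            sim_cfg = SimulationConfig.from_dict(
                dict(config.simulation, seed=config.seed)
            )
            locus_set = generate_locus_set(sim_cfg, out_dir=os.path.join(
                config.out_dir, "simulated_data"))
            _stage(log, "simulate", "generated %d loci", len(locus_set.loci))
        else:
            locus_set = read_locus_set(config.input_dir)
            _stage(log, "load", "read %d loci from %s",
                   len(locus_set.loci), config.input_dir)

        diag = validate_inputs(locus_set.loci)
        for w in diag["warnings"]:
            log.warning("[validate] %s", w)
        if diag["errors"]:
            raise RuntimeError("[validate] " + "; ".join(diag["errors"]))

        loci = ann.annotate_loci(locus_set.loci)
        _stage(log, "annotate", "classified %d loci", len(loci))

        summary_rows = []
        for cls in config.classes:
            st = pg_stats.summarize_class(
                loci, cls, cpg_filter=config.cpg_filter,
                n_boot=min(config.bootstrap_reps, 200),
                fixed_n=config.fixed_n, seed=config.seed,
            )
            summary_rows.append({
                "class": cls, "n_sites": st.n_sites, "S": st.seg_sites,
                "theta_pi_pct": 100 * st.theta_pi, "theta_w_pct": 100 * st.theta_w,
                "tajima_d": st.tajima_d,
                "d_close_pct": None if st.d_close is None else 100 * st.d_close,
                "d_far_pct": None if st.d_far is None else 100 * st.d_far,
                **{f"se_{k}": v for k, v in st.se.items()},
            })
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(os.path.join(config.out_dir, "summary_stats.tsv"),
                       sep="\t", index=False)
        _stage(log, "stats", "summary written (classes=%s, cpg_filter=%s)",
               ",".join(config.classes), config.cpg_filter)

        sfs_rows = []
        for cls in config.classes:
            sfs = build_grouped_folded_sfs(loci, cls, config.cpg_filter)
            for n in sfs.sample_sizes():
                for k, c in enumerate(sfs.spectra[n]):
                    sfs_rows.append({"class": cls, "n": n, "minor_count": k,
                                     "n_sites": c})
        pd.DataFrame(sfs_rows).to_csv(
            os.path.join(config.out_dir, "sfs.tsv"), sep="\t", index=False)
        _stage(log, "sfs", "grouped folded spectra written")

        fis = pg_stats.fis_per_snp(loci)
        pd.DataFrame(
            [{"snp": f.snp_id, "f_is": f.f_is,
              "hom1": f.genotype_counts[0], "het": f.genotype_counts[1],
              "hom2": f.genotype_counts[2]} for f in fis]
        ).to_csv(os.path.join(config.out_dir, "fis.tsv"), sep="\t", index=False)
        _stage(log, "fis", "%d SNP F_IS values", len(fis))

        result = alpha_mod.model_based_alpha_analysis(
            loci,
            neutral_class=config.neutral_reference,
            outgroup=config.outgroup,
            cpg_filter=config.cpg_filter,
            n_boot=config.bootstrap_reps,
            seed=config.seed,
            grid_two_n1=config.grid_two_n1,
        )
        fit = result["fit"]
        est = result["alpha"]
        fit_payload = {
            "gamma_shape": fit.dfe.shape,
            "mean_Nes_weighted": fit.dfe.mean_S,
            "mean_S_internal_N1_scale": fit.mean_S_internal,
            "f0": fit.f0,
            "loglik": fit.loglik,
            "demography": {"n1": fit.demog.n1, "n2": fit.demog.n2, "t": fit.demog.t},
            "weighted_n": fit.weighted_n,
            "weighted_n_convention": fit.details["weighted_n_convention"],
            "nes_class_props_pct": (100 * fit.nes_class_props).tolist(),
            "alpha_model_based": est.alpha,
            "alpha_ci": est.ci,
            "alpha_se": est.se,
            "seed": config.seed,
        }
        with open(os.path.join(config.out_dir, "dfe_fit.json"), "w") as fh:
            json.dump(fit_payload, fh, indent=1)
        _stage(log, "fit-dfe",
               "shape=%.3f meanS=%.3g f0=%.3f alpha=%.3f (boot=%d)",
               fit.dfe.shape, fit.dfe.mean_S, fit.f0, est.alpha, est.n_boot)

        alpha_rows = [{
            "method": "model_based", "neutral": config.neutral_reference,
            "outgroup": config.outgroup, "alpha": est.alpha,
            "ci_low": None if est.ci is None else est.ci[0],
            "ci_high": None if est.ci is None else est.ci[1],
            "se": est.se,
        }]
        for thr, label in ((0.0, "fww_all"), (0.10, "fww_gt10")):
            try:
                fww = alpha_mod.fww_alpha_analysis(
                    loci, neutral_class=config.neutral_reference,
                    outgroup=config.outgroup, cpg_filter=config.cpg_filter,
                    freq_threshold=thr, fixed_n=config.fixed_n,
                    n_boot=config.bootstrap_reps, seed=config.seed,
                )
                e = fww["alpha"]
                alpha_rows.append({
                    "method": label, "neutral": config.neutral_reference,
                    "outgroup": config.outgroup, "alpha": e.alpha,
                    "ci_low": None if e.ci is None else e.ci[0],
                    "ci_high": None if e.ci is None else e.ci[1],
                    "se": e.se,
                })
                _stage(log, "alpha", "%s alpha=%.3f", label, e.alpha)
            except ValueError as exc:
                log.warning("[alpha] %s undefined: %s", label, exc)
        pd.DataFrame(alpha_rows).to_csv(
            os.path.join(config.out_dir, "alpha.tsv"), sep="\t", index=False)
        _stage(log, "done", "all reports written to %s", config.out_dir)
        return {"loci": loci, "summary": summary, "fit": fit,
                "alpha": est, "out_dir": config.out_dir}
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
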