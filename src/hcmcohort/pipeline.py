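"""Pipeline orchestration, table rendering, and the run manifest.

``run_pipeline`` executes the stages (filter/burden -> zygosity ->
classification) in order against a configured cohort, writes the shaped
output tables, and records a run manifest (config snapshot, input
digests, version, seed) so every output is traceable to the exact run
that produced it.  Rounding happens only at render time; stored results
keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .burden import BurdenRow, burden_scan, patient_level_yield, summed_stratum_frequency
from .classify import load_evidence_table, reclassify_catalogue
from .fixtures import egypt_like_fixture
from .io import load_analysis_config, load_cohort, load_variant_catalogue, panel_from_dict
from .simulate import default_spec, simulate_cohort
from .taxonomy import RarityTier
from .types import AnalysisConfig, Cohort, GenePanel
from .zygosity import (
    consanguinity_association,
    detect_biallelic,
    homozygosity_profile,
)

log = logging.getLogger("hcmcohort")

STAGES = ("burden", "zygosity", "classify")


def fmt_pct(x: float, decimals: int = 2) -> str:
    """Render a fraction as a percentage string ('0%' for exact zero)."""
    if x == 0:
        return "0%"
    return f"{100 * x:.{decimals}f}%"


def fmt_count_frac(count: int, total: int, decimals: int = 1) -> str:
    """Render '33.3% (5/15)'-style cells."""
    if total == 0:
        return "0%"
    pct = 100 * count / total
    return f"{pct:.{decimals}f}% ({count}/{total})"


@dataclass
class RunManifest:
    config_snapshot: dict
    input_digests: dict[str, str]
    tool_version: str
    seed: int
    started: str
    finished: Optional[str] = None
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(
    config: Mapping,
) -> tuple[Cohort, GenePanel, AnalysisConfig, dict[str, str]]:
    panel = (
        panel_from_dict(config["panel"]) if "panel" in config else GenePanel()
    )
    if isinstance(config.get("analysis"), str):
        cfg = load_analysis_config(config["analysis"])
    else:
        cfg = AnalysisConfig(**config.get("analysis", {}))
    digests: dict[str, str] = {}
    inputs = config.get("inputs", {})
    if inputs.get("fixture") == "egypt_like":
        cohort, _ = egypt_like_fixture()
    elif "simulate" in inputs:
        sim = inputs["simulate"]
        spec = default_spec(seed=int(sim.get("seed", cfg.seed)))
        cohort = simulate_cohort(spec).cohort
    else:
        missing = [k for k in ("catalogue", "manifest", "genotypes") if k not in inputs]
        if missing:
            raise KeyError(f"config inputs missing required key(s) {missing}")
        for key in ("catalogue", "manifest", "genotypes"):
            digests[key] = _digest(inputs[key])
        catalogue = load_variant_catalogue(inputs["catalogue"])
        cohort = load_cohort(inputs["manifest"], inputs["genotypes"], catalogue)
    return cohort, panel, cfg, digests


def burden_table(rows: Sequence[BurdenRow]) -> pd.DataFrame:
    """Shaped burden-scan table (percentages rendered, counts kept)."""
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in rows],
            "vclass": [r.vclass.value for r in rows],
            "case_freq": [fmt_pct(r.case_freq) for r in rows],
            "control_freq": [fmt_pct(r.control_freq) for r in rows],
            "excess": [fmt_pct(r.excess) for r in rows],
            "p": [r.association.p_value for r in rows],
            "significance": [r.adjusted.flag if r.adjusted else "" for r in rows],
            "gpos_proportion": [
                "" if r.gpos_proportion is None else fmt_pct(r.gpos_proportion)
                for r in rows
            ],
        }
    )


def run_pipeline(
    config_path: str,
    out_dir: Optional[str] = None,
    stages: Optional[Sequence[str]] = None,
) -> str:
    """Execute the configured stages; returns the output directory.

    On any stage error, partial outputs are removed and the error is
    re-raised (the caller maps it to a nonzero exit status).
    """
    with open(config_path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    out_dir = out_dir or config.get("out", "hcmcohort_out")
    stages = tuple(stages or config.get("stages", STAGES))
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; stages are {STAGES}")
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(
        config_snapshot=dict(config),
        input_digests={},
        tool_version=__version__,
        seed=int(config.get("analysis", {}).get("seed", 0))
        if not isinstance(config.get("analysis"), str)
        else 0,
        started=datetime.now(timezone.utc).isoformat(),
    )
    try:
        cohort, panel, cfg, digests = _load_inputs(config)
        manifest.input_digests = digests
        log.info(
            "loaded cohort %s: %d cases / %d controls, %d variants, %d genotypes",
            cohort.name, cohort.n_cases, cohort.n_controls,
            len(cohort.catalogue), len(cohort.genotypes),
        )
        if "burden" in stages:
            rows = burden_scan(cohort, panel, cfg=cfg)
            path = os.path.join(out_dir, "burden.tsv")
            burden_table(rows).to_csv(path, sep="\t", index=False)
            manifest.outputs.append(path)
            n_gpos, frac = patient_level_yield(cohort, panel, cfg=cfg)
            summed = summed_stratum_frequency(cohort, panel, cfg=cfg)
            ypath = os.path.join(out_dir, "yield.tsv")
            pd.DataFrame(
                [
                    {
                        "genotype_positive": n_gpos,
                        "patient_level_yield": fmt_pct(frac, 1),
                        "summed_stratum_frequency": fmt_pct(summed, 1),
                    }
                ]
            ).to_csv(ypath, sep="\t", index=False)
            manifest.outputs.append(ypath)
            log.info("burden: %d strata rows, %d genotype-positive", len(rows), n_gpos)
        if "zygosity" in stages:
            profiles = homozygosity_profile(cohort, panel, cfg)
            zpath = os.path.join(out_dir, "homozygosity.tsv")
            pd.DataFrame(
                {
                    "stratum": [p.stratum for p in profiles],
                    "rare_hom": [
                        fmt_count_frac(p.rare_hom, p.rare_carriers) for p in profiles
                    ],
                    "additional_hom": [
                        fmt_count_frac(p.additional_hom, p.additional_carriers)
                        for p in profiles
                    ],
                    "total_hom": [
                        fmt_count_frac(p.total_hom, p.total_carriers) for p in profiles
                    ],
                }
            ).to_csv(zpath, sep="\t", index=False)
            manifest.outputs.append(zpath)
            try:
                cons = consanguinity_association(cohort, panel, cfg)
                cpath = os.path.join(out_dir, "consanguinity.tsv")
                pd.DataFrame(
                    [
                        {
                            "hom_rate_consanguineous": fmt_count_frac(
                                *cons.hom_rate_consanguineous, 0
                            ),
                            "hom_rate_nonconsanguineous": fmt_count_frac(
                                *cons.hom_rate_nonconsanguineous, 0
                            ),
                            "hom_rate_unknown": fmt_count_frac(
                                *cons.hom_rate_unknown, 1
                            ),
                            "p": cons.association.p_value,
                            "odds_ratio": cons.association.odds_ratio,
                        }
                    ]
                ).to_csv(cpath, sep="\t", index=False)
                manifest.outputs.append(cpath)
            except ValueError as exc:
                log.info("consanguinity association skipped: %s", exc)
            from .types import GeneGroup

            for gene in panel.genes_in_group(GeneGroup.RECESSIVE):
                calls, freq = detect_biallelic(cohort, gene, cfg)
                bpath = os.path.join(out_dir, f"biallelic_{gene}.tsv")
                pd.DataFrame(
                    {
                        "sample_id": [c.sample_id for c in calls],
                        "mechanism": [c.mechanism.value for c in calls],
                        "variant_ids": [";".join(c.variant_ids) for c in calls],
                    }
                ).to_csv(bpath, sep="\t", index=False)
                manifest.outputs.append(bpath)
                log.info("%s biallelic: %d calls (%s)", gene, len(calls), fmt_pct(freq))
        if "classify" in stages:
            evidence_path = config.get("inputs", {}).get("evidence")
            baseline = load_evidence_table(evidence_path) if evidence_path else {}
            results = reclassify_catalogue(cohort, baseline, panel, cfg)
            kpath = os.path.join(out_dir, "classification.tsv")
            pd.DataFrame(
                {
                    "variant_id": list(results),
                    "class_before": [b.klass.label for b, _ in results.values()],
                    "class_after": [a.klass.label for _, a in results.values()],
                    "applied_rules": [
                        ";".join(a.provenance) for _, a in results.values()
                    ],
                }
            ).to_csv(kpath, sep="\t", index=False)
            manifest.outputs.append(kpath)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(os.path.join(out_dir, "manifest.json"))
    return out_dir
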