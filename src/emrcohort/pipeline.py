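"""End-to-end pipeline: generate -> verify -> cohort -> outcomes -> alerts.

Each stage writes its artifact under the configured output directory and
the run closes with a manifest (inputs, derived seeds, package version,
SHA-256 of every output) so that identical configurations reproduce
byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alerts import AlertEngine, AlertRule, load_rules
from .codelist import load_codelist
from .config import RunConfig
from .io import write_extract
from .linkage import verification_report
from .outcomes import (hru_rates, medication_subset, person_time,
                       stratify_by_baseline_exacerbations)
from .phenotyping import CohortSpec, build_cohort
from .synthetic import corrupt_to_source, generate_population

log = logging.getLogger("emrcohort")

__all__ = ["run_pipeline"]

_DEFAULT_RULES = [
    AlertRule(rule_id="respiratory_admission", concepts=["resp_admission"]),
    AlertRule(rule_id="ocs_2_in_30d", concepts=["ocs"], count_min=2, window_days=30),
]


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dictionary."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    codelist = load_codelist(config.codelist_path)
    seeds = _derive_seeds(config.seed, 3)
    outputs: list[Path] = []

    # --- generate ---------------------------------------------------------
    log.info("generating population (n=%d)", config.generator.n_adults)
    params = config.generator.model_copy(update={"seed": seeds[0]})
    truth = generate_population(params, codelist)
    prof_a = config.corruption_a.model_copy(update={"seed": seeds[1]})
    prof_b = config.corruption_b.model_copy(update={"seed": seeds[2]})
    ex_a = corrupt_to_source(truth, prof_a, config.source_a)
    ex_b = corrupt_to_source(truth, prof_b, config.source_b)
    for ex in (ex_a, ex_b):
        paths = write_extract(ex, out / f"extract_{ex.source_name}")
        outputs.extend(paths.values())

    # --- verify -----------------------------------------------------------
    log.info("dual verification of %s vs %s", ex_a.source_name, ex_b.source_name)
    report = verification_report(ex_a, ex_b, registry_total=len(truth.patients),
                                 condition_concept=config.condition_concept,
                                 codelist=codelist)
    rpath = out / "verification_report.json"
    rpath.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    outputs.append(rpath)

    # --- cohorts ----------------------------------------------------------
    cohorts = {}
    flow_all = {}
    for spec in (CohortSpec.asthma(), CohortSpec.copd()):
        log.info("building %s cohort", spec.disease)
        cohort = build_cohort(ex_a, spec, codelist)
        cohorts[spec.disease] = cohort
        cpath = out / f"cohort_{spec.disease}.csv"
        cohort.members.to_csv(cpath, index=False)
        outputs.append(cpath)
        flow_all[spec.disease] = cohort.flow
    fpath = out / "flow.json"
    fpath.write_text(json.dumps(flow_all, indent=2, sort_keys=True) + "\n")
    outputs.append(fpath)

    # --- outcomes ---------------------------------------------------------
    rate_frames = []
    for disease, cohort in cohorts.items():
        if cohort.n == 0:
            continue
        fu = person_time(ex_a.journal, cohort.keys, codelist=codelist)
        strata = {"total": cohort.keys}
        strata.update(stratify_by_baseline_exacerbations(cohort))
        strata["medication_subset"] = medication_subset(cohort)
        rates = hru_rates(cohort, ex_a.journal, strata, codelist, fu)
        rates.insert(0, "cohort", disease)
        rate_frames.append(rates)
    if rate_frames:
        rates = pd.concat(rate_frames, ignore_index=True)
        rpath = out / "rates.csv"
        rates.to_csv(rpath, index=False)
        outputs.append(rpath)

    # --- alerts (replay the journal as daily batches over one month) ------
    rules = load_rules(config.rules_path) if config.rules_path else list(_DEFAULT_RULES)
    engine = AlertEngine(rules, codelist)
    j = ex_a.journal
    window = (pd.Timestamp("2009-01-01"), pd.Timestamp("2009-02-01"))
    feed = j[(j["date"] >= window[0]) & (j["date"] < window[1])]
    apath = out / "alerts.jsonl"
    with open(apath, "w") as fh:
        for day, batch in feed.groupby(feed["date"].dt.normalize()):
            for alert in engine.ingest_batch(batch, day):
                fh.write(json.dumps(alert.to_dict(), sort_keys=True) + "\n")
    outputs.append(apath)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "n_adults": params.n_adults,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs))},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
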