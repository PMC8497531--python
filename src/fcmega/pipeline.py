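"""Stage orchestration: simulate -> features -> mega -> meta -> report.

Each stage reads and writes only documented files under the working
directory, so stages are independently runnable and testable:

    simulate : dataset dir (participants.tsv, atlas.tsv, timeseries/)
    features : features.tsv, exclusions.tsv (+ provenance)
    mega     : mega_networks.tsv [, mega_edges.tsv]
    meta     : meta_networks.tsv, meta_sites.tsv
    report   : concordance.json
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import io as fio
from .cohort import CohortConfig, generate_cohort, records_to_frame
from .features import feature_names, filter_subjects, subject_features
from .mega import compare_groups, edge_group_analysis
from .meta import run_meta, mega_meta_concordance


def run_simulate(config: CohortConfig, out_dir: Path | str) -> Path:
    cohort = generate_cohort(config)
    out_dir = Path(out_dir)
    fio.write_cohort(cohort, out_dir)
    prov = fio.provenance_record(dataclasses.asdict(config), config.seed,
                                 {"n_subjects": len(cohort.records)})
    (out_dir / "provenance.json").write_text(
        json.dumps(fio._jsonable(prov), indent=2, sort_keys=True) + "\n")
    return out_dir


def run_features(data_dir: Path | str, out_dir: Path | str,
                 fd_max: float = 0.55, age_min: float = 18.0,
                 age_max: float = 65.0, between_policy: str = "positive",
                 include_edges: bool = False) -> dict:
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, series, atlas = fio.read_cohort_dir(data_dir)
    kept, excluded = filter_subjects(records, fd_max, age_min, age_max)
    kept_ids = {r.subject_id for r in kept}
    series_kept = [ts for ts in series if ts.subject_id in kept_ids]
    feats, edges = subject_features(series_kept, atlas,
                                    between_policy=between_policy,
                                    include_edges=include_edges)
    reasons: dict[str, int] = {}
    for ex in excluded:
        reasons[f"excluded_{ex.reason}"] = reasons.get(f"excluded_{ex.reason}", 0) + 1
    counts = {"n_input": len(records), **reasons, "n_analysed": len(kept)}
    prov = fio.provenance_record(
        {"fd_max": fd_max, "age_min": age_min, "age_max": age_max,
         "between_policy": between_policy}, None, counts)
    fio.write_results(feats, out_dir / "features.tsv", provenance=prov)
    fio.write_exclusions(excluded, out_dir / "exclusions.tsv")
    participants = records_to_frame(kept)
    participants.to_csv(out_dir / "participants_qc.tsv", sep="\t", index=False)
    if edges is not None:
        pd.DataFrame(edges).to_csv(out_dir / "edges.tsv", sep="\t", index=False,
                                   float_format="%.8g")
    return {"features": feats, "records": participants, "edges": edges,
            "counts": counts, "atlas": atlas}


def run_mega(work_dir: Path | str, transform: str = "inverse_normal",
             alpha: float = 0.05, with_edges: bool = False) -> pd.DataFrame:
    work_dir = Path(work_dir)
    feats = pd.read_csv(work_dir / "features.tsv", sep="\t")
    records = pd.read_csv(work_dir / "participants_qc.tsv", sep="\t",
                          dtype={"subject_id": str, "site_id": str})
    results = compare_groups(feats, records, feature_names("both"),
                             transform=transform, alpha=alpha)
    fio.write_results(results, work_dir / "mega_networks.tsv",
                      provenance=fio.provenance_record(
                          {"transform": transform, "alpha": alpha}, None,
                          {"n_analysed": len(records)}))
    if with_edges:
        edges = pd.read_csv(work_dir / "edges.tsv", sep="\t").to_numpy(float)
        edge_res = edge_group_analysis(edges, feats["subject_id"].tolist(),
                                       records, transform=transform, alpha=alpha)
        fio.write_results(edge_res, work_dir / "mega_edges.tsv")
    return results


def run_meta_stage(work_dir: Path | str, min_per_group: int = 10,
                   transform: str = "inverse_normal",
                   alpha: float = 0.05) -> pd.DataFrame:
    work_dir = Path(work_dir)
    feats = pd.read_csv(work_dir / "features.tsv", sep="\t")
    records = pd.read_csv(work_dir / "participants_qc.tsv", sep="\t",
                          dtype={"subject_id": str, "site_id": str})
    pooled, sites, excluded = run_meta(feats, records, feature_names("both"),
                                       min_per_group=min_per_group,
                                       transform=transform, alpha=alpha)
    fio.write_results(pooled, work_dir / "meta_networks.tsv",
                      provenance=fio.provenance_record(
                          {"min_per_group": min_per_group,
                           "transform": transform, "alpha": alpha}, None,
                          {"n_sites_included": int(pooled["n_sites"].max()),
                           "n_sites_excluded": len(excluded)}))
    fio.write_results(sites, work_dir / "meta_sites.tsv")
    return pooled


def run_report(work_dir: Path | str, alpha: float = 0.05) -> dict:
    work_dir = Path(work_dir)
    mega = pd.read_csv(work_dir / "mega_networks.tsv", sep="\t")
    meta = pd.read_csv(work_dir / "meta_networks.tsv", sep="\t")
    report = mega_meta_concordance(mega, meta, alpha=alpha)
    (work_dir / "concordance.json").write_text(
        json.dumps(fio._jsonable(report), indent=2, sort_keys=True) + "\n")
    return report
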