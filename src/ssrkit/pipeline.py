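"""End-to-end run: validate -> diversity -> distance/PCoA/PhiPT -> key -> assign.

Writes a deterministic report bundle plus a manifest recording the seed,
package version, input checksum, and per-stage timing.  Any stage failure
aborts the run and removes partial outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assignment import AssignmentConfig, assign, candidate_profiles, simulate_critical_deltas
from .distance import cultivar_matrix, distance_matrix, pcoa, phipt, ld_screen
from .diversity import fixed_alleles, group_summary, locus_table
from .io import read_genotypes
from .keying import find_key, render_key
from .model import UNKNOWN, GenotypeTable, allele_frequencies, validate

ALL_STAGES = ("validate", "diversity", "distance", "pcoa", "phipt", "ld", "key", "assign")


@dataclass
class RunConfig:
    input_path: str
    dialect: str = "tidy"
    out_dir: str = "ssrkit_run"
    group_by: str = "cultivar"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    n_perm: int = 999
    key_max_size: int = 4
    key_loci: tuple[str, ...] | None = None
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    force: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(c) for c in row])


def _write_matrix_csv(path: Path, ids: list[str], matrix: np.ndarray) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + ids)
        for name, row in zip(ids, matrix):
            w.writerow([name] + [f"{v:.6g}" for v in row])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict."""
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "input": str(config.input_path),
        "input_sha256": hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest(),
        "stages": {},
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    stage = None
    try:
        table = read_genotypes(config.input_path, config.dialect)
        females = GenotypeTable.from_samples(
            [s for s in table.samples if s.sex != "male" and s.cultivar != UNKNOWN],
            table.locus_names,
        )
        males = [s for s in table.samples if s.sex == "male" or s.cultivar == UNKNOWN]
        dist = None

        for stage in config.stages:
            t0 = time.perf_counter()
            if stage == "validate":
                report = validate(table)
                emit("validation.tsv", lambda p: _write_tsv(
                    p, ["severity", "code", "sample_id", "locus", "message"],
                    [[i.severity, i.code, i.sample_id or "", i.locus or "", i.message]
                     for i in report],
                ))
            elif stage == "diversity":
                stats = locus_table(females, config.group_by)
                emit("diversity_loci.tsv", lambda p: _write_tsv(
                    p, ["group", "locus", "n", "Na", "Ne", "n_genotypes",
                        "Hobs", "Hexp", "UHexp", "F"],
                    [[s.group, s.locus, s.n, s.Na, s.Ne, s.n_genotypes,
                      s.Hobs, s.Hexp, s.UHexp, s.F] for s in stats],
                ))
                summaries = group_summary(stats, females, config.group_by)
                emit("diversity_groups.tsv", lambda p: _write_tsv(
                    p, ["group", "N", "mean_Na", "mean_Ne", "mean_Hobs", "mean_Hexp",
                        "mean_UHexp", "F", "mean_F_polymorphic", "P_pct"],
                    [[g.group, g.N, g.mean_Na, g.mean_Ne, g.mean_Hobs, g.mean_Hexp,
                      g.mean_UHexp, g.F_summary, g.mean_F_polymorphic, g.P_pct]
                     for g in summaries],
                ))
                emit("fixed_alleles.tsv", lambda p: _write_tsv(
                    p, ["locus", "allele", "cultivars"],
                    [[locus, allele, ";".join(cvs)]
                     for locus, allele, cvs in fixed_alleles(females)],
                ))
            elif stage == "distance":
                dist = distance_matrix(females)
                emit("distance_individuals.csv", lambda p: _write_matrix_csv(
                    p, dist.sample_ids, dist.matrix))
                summary = cultivar_matrix(dist, [s.cultivar for s in females.samples])
                emit("distance_cultivars.csv", lambda p: _write_matrix_csv(
                    p, summary.cultivars, summary.matrix))
            elif stage == "pcoa":
                if dist is None:
                    dist = distance_matrix(females)
                summary = cultivar_matrix(dist, [s.cultivar for s in females.samples])
                res = pcoa(summary)
                emit("pcoa_coordinates.csv", lambda p: _write_tsv(
                    p, ["entity"] + [f"axis{k + 1}" for k in range(res.coordinates.shape[1])],
                    [[name] + list(coords) for name, coords in zip(res.ids, res.coordinates)]
                    + [["pct_variation"] + list(res.pct_variation)]
                    + [["cumulative_pct"] + list(res.cumulative_pct)],
                ))
            elif stage == "phipt":
                if dist is None:
                    dist = distance_matrix(females)
                res = phipt(dist, [s.cultivar for s in females.samples],
                            n_perm=config.n_perm, seed=config.seed)
                emit("phipt.json", lambda p: p.write_text(json.dumps({
                    "phi_pt": res.phi_pt, "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "var_among": res.var_among, "var_within": res.var_within,
                }, indent=2) + "\n", encoding="utf-8"))
            elif stage == "ld":
                pvals = ld_screen(females, n_perm=config.n_perm, seed=config.seed)
                emit("ld_pairs.tsv", lambda p: _write_tsv(
                    p, ["locus_a", "locus_b", "p_value"],
                    [[a, b, pv] for (a, b), pv in sorted(pvals.items())],
                ))
            elif stage == "key":
                key = find_key(females, max_size=config.key_max_size,
                               force_loci=list(config.key_loci) if config.key_loci else None)
                emit("identification_key.tsv", lambda p: p.write_text(
                    render_key(key), encoding="utf-8"))
                emit("identification_key.json", lambda p: p.write_text(json.dumps({
                    "loci": key.loci, "unique": key.unique,
                    "total_alleles": key.total_alleles,
                    "collisions": key.collisions,
                    "variant_warnings": key.variant_warnings,
                }, indent=2) + "\n", encoding="utf-8"))
            elif stage == "assign":
                if not males:
                    continue
                freqs = allele_frequencies(females, "all")[0]
                cands = candidate_profiles(females)
                acfg = AssignmentConfig(
                    error_rate=config.assignment.error_rate,
                    n_sim=config.assignment.n_sim,
                    strict_conf=config.assignment.strict_conf,
                    relaxed_conf=config.assignment.relaxed_conf,
                    seed=config.seed,
                )
                critical = simulate_critical_deltas(cands, freqs, acfg)
                results = assign(males, cands, freqs, acfg, critical)
                locality = {s.sample_id: s.locality for s in males}
                emit("assignments.tsv", lambda p: _write_tsv(
                    p, ["collection_site", "query_id", "candidate_cultivar",
                        "profile", "lod", "delta", "confidence"],
                    [[locality[r.query_id], r.query_id, r.best_cultivar or "",
                      r.best_profile_id or "", r.lod, r.delta, r.confidence]
                     for r in results],
                ))
                emit("critical_deltas.json", lambda p: p.write_text(json.dumps({
                    "strict_delta": critical.strict_delta,
                    "relaxed_delta": critical.relaxed_delta,
                    "strict_rate": critical.strict_rate,
                    "relaxed_rate": critical.relaxed_rate,
                    "n_sim": critical.n_sim,
                }, indent=2) + "\n", encoding="utf-8"))
            manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 4)}
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest
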