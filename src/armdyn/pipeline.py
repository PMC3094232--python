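"""Pipeline orchestration: count -> share-test -> fit-intensity -> find-blocks -> fit-blocks.

The pipeline takes marker and inversion tables in the io_maps TSV dialects
plus an explicit arm-pairing table (arm homologies across species are user
configuration, not inferred), runs every stage with recorded seeds, and emits
a machine-readable JSON report shaped like the study's summary tables plus
heat-map and density figures. Identical configs reproduce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import block_rates, blocks, intensity, io_maps, sharing_test, viz

logger = logging.getLogger("armdyn")


@dataclass
class PipelineConfig:
    markers: str = "markers.tsv"
    regions: str | None = "regions.tsv"
    reference_species: str = ""
    species: list[str] = field(default_factory=list)
    arm_pairing: list[dict[str, str]] = field(default_factory=list)   # arm label -> per-species arm
    seed: int = 0
    share_test: dict[str, Any] = field(default_factory=lambda: {"draws": 10_000})
    intensity: dict[str, Any] = field(default_factory=lambda: {
        "run": True, "burnin": 20_000, "samples": 20_000, "chains": 4})
    blocks: dict[str, Any] = field(default_factory=lambda: {"rel_tol": 0.5})
    block_rates: dict[str, Any] = field(default_factory=lambda: {
        "samples": 100_000, "prior": [0.001, 0.001]})
    output_dir: str = "armdyn_out"
    figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.species or not self.reference_species:
            raise io_maps.ArmdynError("config must name species and reference_species")
        if self.reference_species not in self.species:
            raise io_maps.ArmdynError("reference_species must be listed in species")
        for row in self.arm_pairing:
            for sp in self.species:
                if sp not in row:
                    raise io_maps.ArmdynError(f"arm pairing row {row} lacks species {sp!r}")

    def digest(self) -> str:
        """Hash of the analysis-defining fields (not output location/figures)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("output_dir", "figures")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _pair_seed(seed: int, *tags: str) -> int:
    h = hashlib.sha256(("/".join(map(str, tags)) + f"#{seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write ``report.json`` (+ figures) to the output dir.

    Any stage failure aborts with a diagnostic naming the stage. The report
    embeds the config hash and every per-stage seed, so a run is replayable
    from the report alone.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker_maps = io_maps.read_marker_table(config.markers)
    region_sets = io_maps.read_region_table(config.regions) if config.regions else {}

    ref = config.reference_species
    others = [s for s in config.species if s != ref]
    report: dict[str, Any] = {
        "config_hash": config.digest(), "seed": config.seed,
        "sharing_tests": [], "intensity": [], "blocks": {}, "block_rates": {},
    }

    arm_block_stats: dict[str, blocks.BlockStats] = {}
    for row in config.arm_pairing:
        label = row.get("label", row[ref])
        ref_key = (ref, row[ref])
        if ref_key not in marker_maps:
            raise io_maps.ArmdynError(f"stage count: no markers for {ref_key}")

        # --- sharing test + intensity per species pair
        for sp in others:
            key = (sp, row[sp])
            if key not in marker_maps:
                continue
            if ref_key not in region_sets or key not in region_sets:
                continue
            m1, m2 = marker_maps[ref_key], marker_maps[key]
            r1, r2 = region_sets[ref_key], region_sets[key]
            if not r1.inversions or not r2.inversions:
                continue
            seed = _pair_seed(config.seed, "share", ref, sp, label)
            try:
                res = sharing_test.monte_carlo_pvalue(
                    m1, m2, r1, r2, n_draws=int(config.share_test.get("draws", 10_000)),
                    seed=seed)
            except Exception as exc:
                raise io_maps.ArmdynError(f"stage share-test [{label} {ref}/{sp}]: {exc}") from exc
            report["sharing_tests"].append({
                "arm": label, "species": [ref, sp], "statistic": res.statistic,
                "df": res.df, "p_asymptotic": res.p_asymptotic,
                "p_simulated": res.p_simulated, "p_simulated_display": res.format_p_simulated(),
                "n_draws": res.n_draws, "seed": seed,
            })
            if config.figures:
                viz.render_heat_map(res.D * res.sign, res.region_ids1, res.region_ids2,
                                    mode="discrepancy",
                                    path=out_dir / f"discrepancy_{label}_{ref}_{sp}.svg")

            if config.intensity.get("run", True):
                seed_i = _pair_seed(config.seed, "intensity", ref, sp, label)
                spec = intensity.IntensityModelSpec(
                    burnin=int(config.intensity.get("burnin", 20_000)),
                    samples=int(config.intensity.get("samples", 20_000)),
                    chains=int(config.intensity.get("chains", 4)), seed=seed_i)
                try:
                    table = io_maps.count_shared(m1, m2, r1, r2)
                    post = intensity.fit_intensity_model(table, spec)
                    ratio = intensity.connectivity_ratio(post)
                except Exception as exc:
                    raise io_maps.ArmdynError(f"stage fit-intensity [{label} {ref}/{sp}]: {exc}") from exc
                gmean = post.posterior_mean_gamma()
                report["intensity"].append({
                    "arm": label, "species": [ref, sp], "seed": seed_i,
                    "converged": post.converged, "rhat": post.rhat,
                    "pairs": [
                        {"region1": r1_, "region2": r2_,
                         "gamma_mean": float(gmean[i, j]),
                         "p_hot": intensity.hot_probability(post, i, j)}
                        for i, r1_ in enumerate(post.region_ids1)
                        for j, r2_ in enumerate(post.region_ids2)
                    ],
                    "connectivity_ratio": {"mean": ratio.mean,
                                           "ci95": [ratio.ci_low, ratio.ci_high]},
                })
                if config.figures:
                    viz.render_heat_map(gmean, post.region_ids1, post.region_ids2,
                                        mode="intensity",
                                        path=out_dir / f"intensity_{label}_{ref}_{sp}.svg")

        # --- blocks on the reference arm (needs all three species)
        keys = [(sp, row[sp]) for sp in [ref] + others]
        if all(k in marker_maps for k in keys) and len(keys) >= 3:
            maps3 = [blocks.OrderedArmMap.from_marker_map(marker_maps[k]) for k in keys[:3]]
            rel_tol = float(config.blocks.get("rel_tol", 0.5))
            try:
                ab = blocks.find_pairwise_blocks(maps3[0], maps3[1], rel_tol)
                ac = blocks.find_pairwise_blocks(maps3[0], maps3[2], rel_tol)
                bc = blocks.find_pairwise_blocks(maps3[1], maps3[2], rel_tol)
                classified = blocks.classify_blocks(ab, ac, bc, maps=maps3)
            except Exception as exc:
                raise io_maps.ArmdynError(f"stage find-blocks [{label}]: {exc}") from exc
            L = marker_maps[ref_key].arm_length
            stats_ = blocks.block_stats(classified, label, L, reference_species=ref)
            arm_block_stats[label] = stats_
            report["blocks"][label] = {
                "counts": stats_.counts, "total_length": stats_.total_length,
                "mean_length": stats_.mean_length,
                "blocks": [
                    {"members": list(b.members), "class": b.conservation_class,
                     "orientation": b.orientation, "pair": list(b.pair) if b.pair else None,
                     "span": list(b.spans.get(ref, (None, None)))}
                    for b in classified
                ],
            }

    # --- compound Poisson rates per arm
    summaries = []
    for label, stats_ in arm_block_stats.items():
        n_samp = int(config.block_rates.get("samples", 100_000))
        prior = tuple(config.block_rates.get("prior", [0.001, 0.001]))
        try:
            fit_c = block_rates.fit_block_process(
                stats_.counts["fully"], stats_.lengths["fully"], stats_.arm_length,
                prior=prior, n_samples=n_samp, seed=_pair_seed(config.seed, "rates", label, "c"))
            fit_cd = block_rates.fit_block_process(
                stats_.counts["combined"], stats_.lengths["combined"], stats_.arm_length,
                prior=prior, n_samples=n_samp, seed=_pair_seed(config.seed, "rates", label, "cd"))
            fit_c.arm = fit_cd.arm = label
            fit_c.block_set, fit_cd.block_set = "c", "c+d"
            diff = block_rates.disruption_difference(fit_c, fit_cd)
        except Exception as exc:
            raise io_maps.ArmdynError(f"stage fit-blocks [{label}]: {exc}") from exc
        summaries.append(diff)
        report["block_rates"][label] = {
            "c": fit_c.summary(), "c+d": fit_cd.summary(), "diff": diff.summaries,
        }
    if len(summaries) >= 2:
        rank_seed = _pair_seed(config.seed, "rank")
        report["block_rates"]["rank"] = block_rates.rank_disruption(summaries, seed=rank_seed)
        if config.figures:
            viz.render_density({s.arm: s.z for s in summaries}, path=out_dir / "z_density.svg")

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
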