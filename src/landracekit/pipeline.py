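"""End-to-end orchestration: a single YAML config drives
simulate/load -> filter -> statistics, with per-stage seeds derived stably
from a master seed and a manifest recording what ran.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import amova, amova_gametic, variance_captured
from .diversity import WindowSpec, diversity_summary
from .ld import decay_distance, hill_weir_fit, pairwise_ld
from .panel import PanelError, PopulationPanel, filter_panel, read_panel, write_panel
from .phase import phase_persistence, split_half_persistence
from .sfs import expected_neutral_sfs, folded_sfs
from .simulate import SimulationConfig, simulate_panel
from .structure import mrd, neighbor_joining, pcoa

logger = logging.getLogger(__name__)

KNOWN_ANALYSES = {"sfs", "diversity", "amova", "capture", "structure", "ld", "phase"}


def child_seed(master_seed: int, stage: str) -> int:
    """Stage seed derived by stable hashing, independent of stage order."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either ``input`` (vcf + popmap paths) or ``simulate`` (SimulationConfig
    fields) must be present.  ``analyses`` is a list of stage names or
    ``{name: {params}}`` mappings; defaults follow the study conventions
    (1 Mb LD window, r^2 threshold 0.2, 100-kb H windows, 10-kb phase bins,
    1000 permutations).
    """

    outdir: Path
    seed: int = 0
    input: dict | None = None
    simulate: dict | None = None
    filter: dict | None = None
    analyses: list = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "outdir" not in raw:
            raise PanelError("config requires 'outdir'")
        cfg = cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            input=raw.get("input"),
            simulate=raw.get("simulate"),
            filter=raw.get("filter"),
            analyses=raw.get("analyses", []),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def normalized_analyses(self) -> list[tuple[str, dict]]:
        out = []
        for entry in self.analyses:
            if isinstance(entry, str):
                out.append((entry, {}))
            elif isinstance(entry, dict) and len(entry) == 1:
                name, params = next(iter(entry.items()))
                out.append((name, params or {}))
            else:
                raise PanelError(f"malformed analysis entry {entry!r}")
        return out

    def validate(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise PanelError("config requires exactly one of 'input' or 'simulate'")
        for name, _ in self.normalized_analyses():
            if name not in KNOWN_ANALYSES:
                raise PanelError(f"unknown analysis {name!r}; known: {sorted(KNOWN_ANALYSES)}")

    def config_hash(self) -> str:
        # hash the scientific configuration only: two runs that differ just
        # in where they write are the same run
        content = {k: v for k, v in self.raw.items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(content, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _validate_preconditions(cfg: RunConfig, panel_phased_expected: bool) -> None:
    """Pre-flight validation of every requested stage before any computation."""
    for name, params in cfg.normalized_analyses():
        if name in {"phase", "ld"} and not panel_phased_expected:
            raise PanelError(f"analysis {name!r} requires phased input")
        if name == "amova" and int(params.get("n_perms", 1000)) < 0:
            raise PanelError("amova n_perms must be >= 0")


def run(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []
    manifest: dict = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.seed,
        "stages": stages_run,
        "stage_seeds": {},
    }

    if cfg.simulate is not None:
        phased_expected = True
    else:
        phased_expected = bool(cfg.input.get("phased", True))
    _validate_preconditions(cfg, phased_expected)

    def stage_seed(name: str) -> int:
        s = child_seed(cfg.seed, name)
        manifest["stage_seeds"][name] = s
        return s

    try:
        if cfg.simulate is not None:
            sim_cfg = SimulationConfig(**{**cfg.simulate, "seed": stage_seed("simulate")})
            panel, truth = simulate_panel(sim_cfg)
            with open(outdir / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            write_panel(panel, outdir / "panel.vcf", outdir / "popmap.tsv")
            stages_run.append("simulate")
        else:
            panel = read_panel(cfg.input["vcf"], cfg.input["popmap"])
            stages_run.append("load")

        if cfg.filter is not None:
            panel = filter_panel(
                panel,
                min_marker_call_rate=float(cfg.filter.get("min_marker_call_rate", 0.9)),
                min_sample_call_rate=float(cfg.filter.get("min_sample_call_rate", 0.9)),
            )
            with open(outdir / "filter.json", "w") as fh:
                json.dump(panel.meta["filter"], fh, indent=2, sort_keys=True)
            stages_run.append("filter")

        dist_cache = None

        def distances():
            nonlocal dist_cache
            if dist_cache is None:
                dist_cache = mrd(panel)
            return dist_cache

        for name, params in cfg.normalized_analyses():
            seed = stage_seed(name)
            if name == "sfs":
                spectrum = folded_sfs(
                    panel,
                    call_rate_c=float(params.get("call_rate_c", 0.9)),
                    n_reps=int(params.get("n_reps", 1000)),
                    seed=seed,
                )
                expected = expected_neutral_sfs(spectrum.g)
                pd.DataFrame(
                    {
                        "class_index": np.arange(1, spectrum.n_classes + 1),
                        "proportion": spectrum.proportions,
                        "expected_neutral_proportion": expected.proportions,
                    }
                ).to_csv(outdir / "sfs.tsv", sep="\t", index=False)
            elif name == "diversity":
                rows = []
                rng = np.random.default_rng(seed)
                for pop in panel.population_labels:
                    sub = panel.take_samples(panel.individuals_of(pop))
                    s = diversity_summary(
                        sub,
                        window=WindowSpec(int(params.get("window_bp", 100_000)),
                                          int(params.get("min_snps", 5))),
                        n_perms=int(params.get("n_perms", 1000)),
                        seed=rng.integers(2**31),
                    )
                    rows.append(
                        dict(population=pop, PP=s.PP, pi=s.pi_mean, H=s.H_mean,
                             n_windows=s.n_windows, Fis=s.Fis, Fis_p=s.Fis_p)
                    )
                pd.DataFrame(rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
            elif name == "amova":
                if panel.phased:
                    res = amova_gametic(panel, n_perms=int(params.get("n_perms", 1000)), seed=seed)
                else:
                    res = amova(distances().values, panel.populations,
                                n_perms=int(params.get("n_perms", 1000)), seed=seed)
                with open(outdir / "amova.json", "w") as fh:
                    json.dump(
                        {k: v for k, v in res.__dict__.items()}, fh, indent=2, sort_keys=True
                    )
            elif name == "capture":
                l_values = list(params.get("l_values", [1, 2, 3, 4, 5]))
                curve = variance_captured(
                    distances().values, panel.populations, l_values,
                    n_repeats=int(params.get("n_repeats", 200)), seed=seed,
                )
                rows = []
                for l in l_values:
                    v = curve.distributions[l]
                    rows.append(
                        dict(l=l, mean=v.mean(), q25=np.quantile(v, 0.25),
                             median=np.median(v), q75=np.quantile(v, 0.75), n=v.size)
                    )
                pd.DataFrame(rows).to_csv(outdir / "capture_curve.tsv", sep="\t", index=False)
            elif name == "structure":
                d = distances()
                d.to_frame().to_csv(outdir / "mrd.tsv", sep="\t")
                coords = pcoa(d, k=int(params.get("k", 3)))
                pd.DataFrame(
                    coords.axes,
                    index=coords.labels,
                    columns=[f"PCo{i + 1}" for i in range(coords.axes.shape[1])],
                ).to_csv(outdir / "pcoa.tsv", sep="\t")
                np.savetxt(outdir / "pcoa_eigenvalues.tsv", coords.eigenvalues, delimiter="\t")
                if d.n >= 3:
                    (outdir / "njt.nwk").write_text(neighbor_joining(d) + "\n")
            elif name == "ld":
                table = pairwise_ld(
                    panel.to_haplotype_set(), int(params.get("max_dist_bp", 1_000_000))
                )
                table.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
                fit = hill_weir_fit(table, n_gametes=2 * panel.n_individuals)
                dd = decay_distance(fit, float(params.get("threshold", 0.2)))
                with open(outdir / "ld_decay.json", "w") as fh:
                    json.dump(
                        dict(rho_per_bp=fit.rho_per_bp, n_gametes=fit.n_gametes,
                             rss=fit.rss, n_pairs=fit.n_pairs,
                             decay_distance_bp=dd.distance_bp if np.isfinite(dd.distance_bp) else None,
                             status=dd.status, mean_r2=float(table["r2"].mean())),
                        fh, indent=2, sort_keys=True,
                    )
            elif name == "phase":
                pops = panel.population_labels
                if len(pops) >= 2:
                    a = panel.take_samples(panel.individuals_of(pops[0]))
                    b = panel.take_samples(panel.individuals_of(pops[1]))
                    pp = phase_persistence(
                        a.to_haplotype_set(), b.to_haplotype_set(),
                        int(params.get("max_dist_bp", 1_000_000)),
                        int(params.get("bin_bp", 10_000)),
                    )
                    pp.table.to_csv(outdir / "phase_between.tsv", sep="\t", index=False)
                pop0 = pops[0]
                if len(panel.individuals_of(pop0)) >= 8:
                    sh = split_half_persistence(
                        panel, pop0, repeats=int(params.get("repeats", 20)), seed=seed,
                        max_dist_bp=int(params.get("max_dist_bp", 1_000_000)),
                        bin_bp=int(params.get("bin_bp", 10_000)),
                    )
                    sh.mean_table.to_csv(outdir / "phase_split_half.tsv", sep="\t", index=False)
            stages_run.append(name)
    except Exception:
        manifest["failed_after"] = stages_run[-1] if stages_run else None
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
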