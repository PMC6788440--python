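"""End-to-end orchestration: survey -> alpha -> MDE -> beta -> endemism.

Each stage reads only files written by earlier stages into the output
directory, so a later stage can be re-run alone and reproduce its
outputs.  A manifest (JSON) records the package version, resolved
configuration, per-stage output files with SHA-256 hashes and row
counts, and the seeds of every stochastic stage; identical
configurations produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alpha import diversity_profile
from .beta import multisite_partition, nj_tree, pairwise_partition, to_distance_matrix, write_newick
from .endemism import bootstrap_envelope, endemic_removal_test, endemism_profile
from .exceptions import ParameterError
from .mde import compare_observed, discretize_ranges, range_shuffle
from .survey import (
    build_abundance_matrix,
    filter_records,
    read_survey,
    trap_success,
    write_survey,
)
from .synth import SyntheticConfig, paperlike_preset, simulate_survey

log = logging.getLogger("elevdiv")

STAGES = ("survey", "alpha", "mde", "beta", "endemism")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Either ``records``/``efforts``/``meta`` point at survey files in
    the :func:`elevdiv.survey.read_survey` schema, or ``synthetic`` is
    true and the survey is simulated (from ``synthetic_config`` merged
    over the documented preset).
    """

    outdir: str = "elevdiv_run"
    synthetic: bool = True
    synthetic_config: dict = field(default_factory=dict)
    records: str | None = None
    efforts: str | None = None
    meta: str | None = None
    include_arboreal: bool = False
    include_pitfall: bool = False
    include_recaptures: bool = False
    band_width: float = 50.0
    mde_reps: int = 5000
    mde_boundaries: str = "soft"
    bootstrap_reps: int = 1000
    bootstrap_unit: str = "species"
    permutation_reps: int = 5000
    seed: int = 0

    def validate(self) -> "RunConfig":
        for name in ("mde_reps", "bootstrap_reps", "permutation_reps"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.band_width <= 0:
            raise ParameterError("band_width must be positive")
        if not self.synthetic and self.records is None:
            raise ParameterError("either synthetic=true or records= must be given")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _table_rows(path: Path) -> int | None:
    if path.suffix == ".csv":
        with open(path) as fh:
            return max(sum(1 for _ in fh) - 1, 0)
    return None


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}}

    def record(self, stage: str, outputs: list[Path], seeds: dict | None = None):
        self.data["stages"][stage] = {
            "outputs": [
                {
                    "file": p.name,
                    "sha256": _sha256(p),
                    "rows": _table_rows(p),
                }
                for p in outputs
            ],
            "seeds": seeds or {},
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _load_filtered(outdir: Path):
    ds = read_survey(
        outdir / "records.csv", outdir / "efforts.csv", outdir / "meta.csv"
    )
    return ds


def _stage_survey(cfg: RunConfig, outdir: Path, manifest: _Manifest):
    if cfg.synthetic:
        base = dataclasses.asdict(paperlike_preset())
        base.update(cfg.synthetic_config)
        scfg = SyntheticConfig(**base)
        ds, truth = simulate_survey(scfg, seed=cfg.seed)
        truth.to_json(outdir / "truth.json")
    else:
        ds = read_survey(cfg.records, cfg.efforts, cfg.meta)
        truth = None
    ds = filter_records(
        ds,
        include_arboreal=cfg.include_arboreal,
        include_pitfall=cfg.include_pitfall,
        include_recaptures=cfg.include_recaptures,
    )
    paths = write_survey(ds, outdir)
    ts_loc = trap_success(ds, group_by="location")
    ts_mt = trap_success(ds, group_by="mountain")
    ts_loc.to_csv(outdir / "trap_success_location.csv", index=False)
    ts_mt.to_csv(outdir / "trap_success_mountain.csv", index=False)
    (outdir / "provenance.json").write_text(json.dumps(ds.provenance, indent=1))
    outputs = list(paths.values()) + [
        outdir / "trap_success_location.csv",
        outdir / "trap_success_mountain.csv",
        outdir / "provenance.json",
    ]
    if truth is not None:
        outputs.append(outdir / "truth.json")
    manifest.record("survey", outputs, seeds={"survey": cfg.seed})


def _stage_alpha(cfg: RunConfig, outdir: Path, manifest: _Manifest):
    ds = _load_filtered(outdir)
    am = build_abundance_matrix(ds)
    prof = diversity_profile(am)
    prof.to_csv(outdir / "alpha_diversity.csv", index=False)
    manifest.record("alpha", [outdir / "alpha_diversity.csv"])


def _stage_mde(cfg: RunConfig, outdir: Path, manifest: _Manifest):
    ds = _load_filtered(outdir)
    am = build_abundance_matrix(ds)
    outputs = []
    for i, mountain in enumerate(ds.mountains()):
        domain, ranges = discretize_ranges(ds, cfg.band_width, mountain=mountain)
        env = range_shuffle(
            ranges, domain, reps=cfg.mde_reps, boundaries=cfg.mde_boundaries,
            seed=cfg.seed + 1000 + i,
        )
        sub = am.for_mountain(mountain)
        observed = pd.DataFrame(
            {
                "site": [s[1] for s in sub.sites],
                "elevation": sub.site_elevations.to_numpy(),
                "richness": (sub.counts > 0).sum(axis=1).to_numpy(),
            }
        )
        comp = compare_observed(observed, env)
        p_env = outdir / f"mde_envelope_{mountain}.csv"
        p_cmp = outdir / f"mde_observed_{mountain}.csv"
        env.table.to_csv(p_env, index=False)
        comp.to_csv(p_cmp, index=False)
        outputs += [p_env, p_cmp]
    manifest.record(
        "mde", outputs,
        seeds={m: cfg.seed + 1000 + i for i, m in enumerate(ds.mountains())},
    )


def _stage_beta(cfg: RunConfig, outdir: Path, manifest: _Manifest):
    ds = _load_filtered(outdir)
    im = build_abundance_matrix(ds).to_incidence()
    outputs = []
    multi = {}
    for mountain in ds.mountains():
        part = multisite_partition(im.for_mountain(mountain))
        multi[mountain] = {
            "beta_sor": part.beta_sor,
            "beta_sim": part.beta_sim,
            "beta_sne": part.beta_sne,
            "n_sites": part.n_sites,
            "n_species": part.n_species,
        }
    p_multi = outdir / "beta_multisite.json"
    p_multi.write_text(json.dumps(multi, indent=1, sort_keys=True))
    outputs.append(p_multi)
    pw = pairwise_partition(im)  # pooled across mountains, for clustering
    for name, tabl in (("sor", pw.sor), ("sim", pw.sim), ("sne", pw.sne)):
        p = outdir / f"beta_pairwise_{name}.csv"
        tabl.to_csv(p)
        outputs.append(p)
    tree = nj_tree(to_distance_matrix(pw.sor))
    p_tree = outdir / "nj_sites.nwk"
    write_newick(tree, p_tree)
    outputs.append(p_tree)
    manifest.record("beta", outputs)


def _stage_endemism(cfg: RunConfig, outdir: Path, manifest: _Manifest):
    ds = _load_filtered(outdir)
    am = build_abundance_matrix(ds)
    prof = endemism_profile(am, ds.meta)
    prof.to_csv(outdir / "endemism_profile.csv", index=False)
    env = bootstrap_envelope(
        am, ds.meta, reps=cfg.bootstrap_reps, unit=cfg.bootstrap_unit,
        seed=cfg.seed + 2000,
    )
    env.table.to_csv(outdir / "endemism_bootstrap.csv", index=False)
    results = {}
    im = am.to_incidence()
    for i, mountain in enumerate(ds.mountains()):
        res = endemic_removal_test(
            im.for_mountain(mountain), ds.meta,
            reps=cfg.permutation_reps, seed=cfg.seed + 3000 + i,
        )
        results[mountain] = {
            "observed": {
                "beta_sim": res.observed.beta_sim,
                "beta_sne": res.observed.beta_sne,
                "beta_sor": res.observed.beta_sor,
            },
            "full": {
                "beta_sim": res.full.beta_sim,
                "beta_sne": res.full.beta_sne,
                "beta_sor": res.full.beta_sor,
            },
            "p_sim": res.p_sim,
            "p_sne": res.p_sne,
            "p_sor": res.p_sor,
            "direction_sim": res.direction_sim,
            "direction_sne": res.direction_sne,
            "n_endemic": res.n_endemic,
            "n_non_endemic": res.n_non_endemic,
            "reps": res.reps,
            "seed": res.seed,
            "null_summary": res.null_summary().to_dict(orient="records"),
        }
    p_res = outdir / "endemic_removal.json"
    p_res.write_text(json.dumps(results, indent=1, sort_keys=True))
    outputs = [
        outdir / "endemism_profile.csv",
        outdir / "endemism_bootstrap.csv",
        p_res,
    ]
    manifest.record(
        "endemism", outputs,
        seeds={"bootstrap": cfg.seed + 2000,
               **{m: cfg.seed + 3000 + i for i, m in enumerate(ds.mountains())}},
    )


_STAGE_FNS = {
    "survey": _stage_survey,
    "alpha": _stage_alpha,
    "mde": _stage_mde,
    "beta": _stage_beta,
    "endemism": _stage_endemism,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> Path:
    """Run the requested stages (all of them by default).

    Returns the output directory.  Any stage failure aborts the run
    with the stage name attached to the exception.
    """
    cfg.validate()
    stages = tuple(stages) if stages is not None else STAGES
    bad = set(stages) - set(STAGES)
    if bad:
        raise ParameterError(f"unknown stage(s): {sorted(bad)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.resolved.yml")
    manifest = _Manifest(outdir)
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FNS[stage](cfg, outdir, manifest)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
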