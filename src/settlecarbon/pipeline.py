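"""Resumable clean → reconcile → carbon → temporal → report pipeline.

Each stage reads its inputs from disk, writes its outputs, and records a
manifest entry (stage name, parameters, input file hashes, row counts).  A
rerun with unchanged inputs and parameters skips completed stages; a hash
mismatch re-executes the stage.  Every tolerance and the rounding mode are
surfaced in the YAML config — there are no hidden constants.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import carbon as carbon_mod
from . import cleaning, geodata, reconcile, reporting, temporal
from .geodata import CarbonClassTable, read_registry, read_vector_layer, write_vector_layer

log = logging.getLogger(__name__)

STAGES = ("clean", "reconcile", "carbon", "temporal", "report")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    settlements: str
    registry: str
    region: str
    prodes: str
    pmdbbs: str
    carbon_map: str
    carbon_table: str
    out_dir: str
    region_reference: dict = field(default_factory=dict)
    sliver_ha: float = reconcile.DEFAULT_SLIVER_HA
    hydro_class_id: object = 90
    urban_class_id: object = 91
    rounding: str = "half-away-from-zero"
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        for key in ("settlements", "registry", "region", "prodes", "pmdbbs",
                    "carbon_map", "carbon_table"):
            if not Path(getattr(cfg, key)).exists():
                raise ConfigError(f"input path for {key!r} does not exist: {getattr(cfg, key)}")
        if cfg.sliver_ha <= 0:
            raise ConfigError("sliver_ha must be positive")
        return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_signature(inputs: list[Path], params: dict) -> str:
    payload = {str(p): _hash_file(p) for p in inputs}
    payload["params"] = params
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    # paths of stage outputs
    def _p(self, name: str) -> Path:
        return self.out / name

    def _run_stage(self, name, inputs, outputs, params, fn):
        sig = _stage_signature([Path(p) for p in inputs], params)
        entry = self.manifest.get(name)
        if entry and entry["signature"] == sig and all(Path(o).exists() for o in outputs):
            ok = all(
                _hash_file(Path(o)) == h for o, h in entry["outputs"].items()
            )
            if ok:
                log.info("stage %s: up to date, skipped", name)
                entry["skipped"] = True
                return False
        t0 = time.time()
        try:
            counts = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        self.manifest[name] = {
            "signature": sig,
            "params": params,
            "outputs": {str(o): _hash_file(Path(o)) for o in outputs},
            "row_counts": counts,
            "elapsed_s": round(time.time() - t0, 3),
            "skipped": False,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        log.info("stage %s: done in %.1f s", name, time.time() - t0)
        return True

    # --- stages ------------------------------------------------------------

    def stage_clean(self):
        cfg = self.cfg
        out_layer, out_log = self._p("settlements_clean.geojson"), self._p("cleaning_log.csv")

        def fn():
            layer = read_vector_layer(cfg.settlements, ("settlement_id", "category"))
            registry = read_registry(cfg.registry)
            region = read_vector_layer(cfg.region)["geometry"].iloc[0]
            cleaned, decisions = cleaning.clean_settlements(layer, registry, region)
            write_vector_layer(cleaned, out_layer)
            cleaning.decisions_frame(decisions).to_csv(out_log, index=False)
            return {"kept": len(cleaned), "decisions": len(decisions)}

        return self._run_stage(
            "clean", [cfg.settlements, cfg.registry, cfg.region],
            [out_layer, out_log], {}, fn,
        )

    def stage_reconcile(self):
        cfg = self.cfg
        inp = self._p("settlements_clean.geojson")
        out = self._p("fragments.geojson")

        def fn():
            settlements = read_vector_layer(inp)
            prodes = read_vector_layer(cfg.prodes, ("prodes_class",))
            pmdbbs = read_vector_layer(cfg.pmdbbs)
            carbon_map = read_vector_layer(cfg.carbon_map, ("carbon_class",))
            frags = reconcile.reconcile(
                settlements, prodes, pmdbbs, carbon_map,
                hydro_class_id=cfg.hydro_class_id, urban_class_id=cfg.urban_class_id,
                sliver_ha=cfg.sliver_ha,
            )
            write_vector_layer(frags, out)
            return {"fragments": len(frags)}

        return self._run_stage(
            "reconcile", [inp, cfg.prodes, cfg.pmdbbs, cfg.carbon_map], [out],
            {"sliver_ha": cfg.sliver_ha}, fn,
        )

    def stage_carbon(self):
        cfg = self.cfg
        inp = self._p("fragments.geojson")
        out = self._p("accounts.csv")

        def fn():
            frags = read_vector_layer(inp, ("final_class",))
            table = CarbonClassTable.read_csv(cfg.carbon_table)
            registry = read_registry(cfg.registry)
            acc = carbon_mod.settlement_accounts(carbon_mod.attach_density(frags, table))
            acc = acc.merge(
                registry[["settlement_id", "category", "state", "group"]],
                on="settlement_id",
            )
            acc.to_csv(out, index=False)
            return {"accounts": len(acc)}

        return self._run_stage(
            "carbon", [inp, cfg.carbon_table, cfg.registry], [out], {}, fn,
        )

    def stage_temporal(self):
        cfg = self.cfg
        inp = self._p("fragments.geojson")
        outs = [self._p("series.csv"), self._p("rates.csv"), self._p("family.csv")]

        def fn():
            frags = read_vector_layer(inp, ("final_class",))
            registry = read_registry(cfg.registry)
            table = CarbonClassTable.read_csv(cfg.carbon_table)
            eligible, _ = temporal.eligibility_filter(registry, frags, "pre_post")
            series = temporal.build_series(eligible, frags, table)
            pd.DataFrame([
                {"settlement_id": sid,
                 "original_forest_km2": s.original_forest_km2,
                 "forest_at_creation_km2": s.forest_at_creation_km2}
                for sid, s in series.items()
            ]).to_csv(outs[0], index=False)
            temporal.period_rates(eligible, series).to_csv(outs[1], index=False)
            fam, _ = temporal.eligibility_filter(registry, frags, "family", series)
            fam_series = temporal.build_series(fam, frags, table)
            temporal.family_rates(fam, fam_series).to_csv(outs[2], index=False)
            return {"series": len(series), "family": len(fam)}

        return self._run_stage(
            "temporal", [inp, cfg.registry, cfg.carbon_table], outs, {}, fn,
        )

    def stage_report(self):
        cfg = self.cfg
        inp = self._p("accounts.csv")
        outs = [self._p("landcover_table.csv"), self._p("exclusions_table.csv"),
                self._p("census.csv"), self._p("shares.json")]

        def fn():
            acc = pd.read_csv(inp)
            ref = reporting.RegionReference(**cfg.region_reference)
            lc = reporting.landcover_table(acc)
            lc.to_csv(outs[0], index=False)
            reporting.exclusions_table(acc).to_csv(outs[1], index=False)
            census = reporting.threshold_census(acc)
            pd.concat(
                [df.assign(census=name) for name, df in census.items()]
            ).to_csv(outs[2], index=False)
            total_lc = lc[lc["category"] == "Total"].iloc[0]
            total_carbon = acc[["lost_MgC", "remaining_MgC", "premodern_MgC"]].sum()
            shares = reporting.region_shares(total_lc, total_carbon, ref)
            Path(outs[3]).write_text(json.dumps(shares, indent=1, sort_keys=True))
            return {"categories": len(lc) - 1}

        return self._run_stage("report", [inp], outs, cfg.region_reference, fn)

    def run(self, from_stage: str | None = None) -> dict:
        order = list(STAGES)
        if from_stage:
            if from_stage not in order:
                raise ConfigError(f"unknown stage {from_stage!r}")
            # force re-execution from this stage onward
            for s in order[order.index(from_stage):]:
                self.manifest.pop(s, None)
        for s in order:
            if s not in self.cfg.stages:
                continue
            getattr(self, f"stage_{s}")()
        return self.manifest


def run(config: PipelineConfig, from_stage: str | None = None) -> dict:
    """Run the pipeline; returns the manifest.  Exit-code semantics for the
    CLI: 0 ok, 2 config error, 3 stage failure."""
    return Pipeline(config).run(from_stage)
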