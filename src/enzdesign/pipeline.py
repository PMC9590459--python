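"""End-to-end orchestration: config validation, design run, quantify run.

A run reads the alignment, weights it, builds the PSSM and the Potts model,
classifies the structural environment, enumerates evidence-backed candidate
variants, clusters them with PAM30 distances, and selects per-cluster
representatives.  Reports embed the full parameter set and content hashes of
the inputs so a run is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field as dc_field
from typing import Any

import yaml

from enzdesign import conservation, coevolution, msquant, structure, variants
from enzdesign.errors import EnzdesignError, InputError, ParameterError, ValidationError

logger = logging.getLogger(__name__)


class StageError(EnzdesignError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Validated design-run configuration (flat keys, YAML-loadable)."""

    alignment: str
    structure: str | None = None
    alignment_format: str | None = None
    target_id: str | None = None  # defaults to the first alignment row
    ligand_names: list[str] = dc_field(default_factory=lambda: ["HEM"])
    external_scores: str | None = None
    alias_table: str | None = None
    output_dir: str = "."
    alpha: float = 1.0
    identity_threshold: float = 0.8
    lambda_h: float = 0.01
    lambda_J: float | None = None
    max_iter: int = 500
    tol: float = 1e-5
    k_pairs: int | None = None
    surface_min: float = 0.25
    buried_max: float = 0.05
    pocket_cutoff: float = 6.0
    cluster_k: int = 8
    env_filter: str = "all"
    alphabet: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "alignment" not in raw:
            raise ValidationError("config requires an 'alignment' path")
        return cls(**raw)

    def validate(self) -> None:
        for label, path in (
            ("alignment", self.alignment),
            ("structure", self.structure),
            ("external_scores", self.external_scores),
            ("alias_table", self.alias_table),
        ):
            if path is not None and not os.path.exists(path):
                raise ValidationError(f"{label} file not found: {path}")
        if not 0 < self.identity_threshold <= 1:
            raise ValidationError("identity_threshold must be in (0, 1]")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.surface_min <= self.buried_max:
            raise ValidationError("surface_min must exceed buried_max")
        if self.cluster_k < 1:
            raise ValidationError("cluster_k must be >= 1")
        if self.env_filter not in ("all", "surface", "pocket"):
            raise ValidationError(f"unknown env_filter {self.env_filter!r}")


@dataclass
class DesignReport:
    candidates: variants.VariantSet
    assignment: variants.ClusterAssignment
    representatives: list[variants.Variant]
    provenance: dict[str, Any]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except EnzdesignError as exc:
                raise StageError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name, time.time() - t0)
            return result

        return wrapped

    return deco


def _load_external_scores(path: str) -> dict[str, float]:
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")[:2]
            scores[name] = float(value)
    return scores


def run_design(config: RunConfig) -> DesignReport:
    """Execute read → weights → PSSM → Potts → environment → enumerate →
    cluster → representatives, writing report files under ``output_dir``."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    prov: dict[str, Any] = {
        "parameters": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "input_hashes": {"alignment": _sha256(config.alignment)},
    }
    if config.structure:
        prov["input_hashes"]["structure"] = _sha256(config.structure)

    aln = _stage("read_alignment")(conservation.read_alignment)(
        config.alignment, config.alignment_format
    )
    if config.target_id is None:
        target_row = aln.rows[0]
        prov["target_id"] = aln.ids[0]
    else:
        try:
            target_row = aln.rows[aln.ids.index(config.target_id)]
        except ValueError:
            raise StageError(
                "read_alignment", InputError(f"target id {config.target_id!r} not in alignment")
            )
        prov["target_id"] = config.target_id
    if "-" in target_row:
        raise StageError("read_alignment", InputError("target row must be gap-free"))

    w = _stage("compute_weights")(conservation.compute_weights)(aln, config.identity_threshold)
    prov["neff"] = w.neff

    pssm = _stage("compute_pssm")(conservation.compute_pssm)(aln, w, config.alpha)
    pssm_subs = conservation.positive_substitutions(pssm, target_row)

    model = _stage("fit_potts")(coevolution.fit_potts)(
        aln,
        w,
        lambda_h=config.lambda_h,
        lambda_J=config.lambda_J,
        max_iter=config.max_iter,
        tol=config.tol,
        alphabet=config.alphabet,
    )
    prov["potts_converged"] = model.converged
    prov["potts_grad_norm"] = model.grad_norm
    scores = coevolution.coupling_scores(model)
    coev_subs = coevolution.coevolved_substitutions(model, scores, target_row, config.k_pairs)

    env_by_residue: dict[int, structure.ResidueEnvironment] = {}
    if config.structure:
        s = _stage("read_structure")(structure.read_structure)(
            config.structure, config.ligand_names
        )
        areas = _stage("atom_sasa")(structure.atom_sasa)(s)
        rsa = structure.residue_rsa(s, areas)
        envs = structure.classify_residues(
            s, rsa, config.surface_min, config.buried_max, config.pocket_cutoff
        )
        env_by_residue = {e.residue_number: e for e in envs}
        structure.write_environment_tsv(envs, os.path.join(config.output_dir, "environment.tsv"))

    vs = _stage("enumerate_candidates")(variants.enumerate_candidates)(
        target_row, pssm_subs, coev_subs, env_by_residue, config.env_filter
    )
    if not vs.variants:
        raise StageError("enumerate_candidates", InputError("no candidate variants found"))
    if config.external_scores:
        external = _load_external_scores(config.external_scores)
        for v in vs.variants:
            if v.name in external:
                v.score = external[v.name]

    k = min(config.cluster_k, len(vs.variants))
    if k < config.cluster_k:
        logger.warning("only %d candidates; clustering with k=%d", len(vs.variants), k)
    ca = _stage("cluster_variants")(variants.cluster_variants)(vs, k)
    reps = variants.select_representatives(ca)

    conservation.write_pssm_tsv(pssm, target_row, os.path.join(config.output_dir, "pssm.tsv"))
    coevolution.write_couplings_tsv(scores, os.path.join(config.output_dir, "couplings.tsv"))
    variants.write_variant_report(vs, ca, reps, os.path.join(config.output_dir, "candidates.tsv"))
    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(
            {
                "provenance": prov,
                "n_candidates": len(vs.variants),
                "k": k,
                "representatives": [v.name for v in reps],
            },
            fh,
            indent=2,
            default=str,
        )
    return DesignReport(candidates=vs, assignment=ca, representatives=reps, provenance=prov)


# ---------------------------------------------------------------------------
# quantification runs


@dataclass
class QuantConfig:
    """Configuration of a quantification run.

    ``compounds`` maps compound name → {formula, adduct}; ``curves`` maps
    compound name → list of [concentration, area] points;
    ``shared_curve_map`` routes a compound to another compound's curve.
    """

    spectra: str
    compounds: dict[str, dict[str, str]]
    curves: dict[str, list[list[float]]]
    shared_curve_map: dict[str, str] = dc_field(default_factory=dict)
    tol_ppm: float = 20.0
    window: tuple[float, float] | None = None
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str) -> "QuantConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spectra", "compounds", "curves"):
            if key not in raw:
                raise ValidationError(f"quant config requires {key!r}")
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def validate(self) -> None:
        if not os.path.exists(self.spectra):
            raise ValidationError(f"spectra file not found: {self.spectra}")
        for compound in self.compounds:
            curve_id = self.shared_curve_map.get(compound, compound)
            if curve_id not in self.curves:
                raise ValidationError(f"compound {compound!r} has no curve ({curve_id!r})")


def run_quantify(config: QuantConfig) -> tuple[dict[str, float], dict[str, float]]:
    """EIC → peak areas → standard curves → yields → percentages."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    series = _stage("read_spectra")(msquant.read_spectra_csv)(config.spectra)
    window = config.window or (float(series.times[0]), float(series.times[-1]))

    areas: dict[str, float] = {}
    for name, info in config.compounds.items():
        formula = msquant.MolecularFormula.parse(info["formula"])
        mz = msquant.adduct_mz(formula, info.get("adduct", "[M+H]+"))
        eic = msquant.extract_eic(series, mz, config.tol_ppm)
        areas[name] = msquant.integrate_peak(eic, window)

    curves = {
        cid: msquant.fit_standard_curve([(p[0], p[1]) for p in pts], cid)
        for cid, pts in config.curves.items()
    }
    yields, percentages = _stage("quantify")(msquant.quantify_and_normalize)(
        areas, curves, config.shared_curve_map
    )
    msquant.write_quant_tsv(yields, percentages, os.path.join(config.output_dir, "quant.tsv"))
    return yields, percentages
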