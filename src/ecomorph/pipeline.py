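"""Pipeline orchestration: traits -> categories -> diet -> characters -> stats.

``run_pipeline`` executes whichever stages its configuration provides inputs
for, in dependency order, and writes a machine-readable JSON report plus a
run manifest (config snapshot, input checksums, seeds, stage statuses,
output paths).  A stage failure is recorded with a stage-tagged error and
does not abort independent stages; dependent stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparative, datasets, diet, io, morpho, prey, trees

__all__ = ["RunManifest", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_status: dict[str, str] = field(default_factory=dict)
    stage_errors: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "input_checksums": self.input_checksums,
            "stage_status": self.stage_status,
            "stage_errors": self.stage_errors,
            "outputs": sorted(self.outputs),
        }


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages and return the report dictionary.

    Configuration blocks (all optional; a stage without inputs is skipped):

    - ``prey``: ``traits`` (CSV path or ``"packaged"``), ``dialect``
      (``d2``/``d``), ``k`` (``"auto"`` or int), ``k_max``, ``names``
      (category labels in canonical group order).
    - ``diet``: ``records`` (long CSV, needs the prey stage) or
      ``category_importance`` (wide CSV or ``"packaged"``), ``tie_rule``.
    - ``morphology``: ``measurements`` CSV.
    - ``comparative``: ``tree`` Newick path, ``nsim``, ``groupings``
      (subset of ``habitat``/``synthetic``/``coarse``).
    - ``seed``: base seed for every stochastic stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    report: dict = {"seed": seed}

    for key in ("traits", "records", "category_importance", "measurements", "tree"):
        for block in config.values():
            if isinstance(block, dict) and isinstance(block.get(key), str):
                p = block[key]
                if p != "packaged" and Path(p).exists():
                    manifest.input_checksums[p] = _checksum(p)

    cats = None
    assignments = None
    profiles = None
    z_table = None

    # ---- prey categorization ----
    pc = config.get("prey")
    if pc:
        try:
            matrix = (
                datasets.load_prey_traits()
                if pc.get("traits", "packaged") == "packaged"
                else io.read_prey_traits(pc["traits"])
            )
            dialect = pc.get("dialect", "d2")
            d = prey.euclidean_distance_matrix(matrix)
            dendro = prey.ward_cluster(d, dialect=dialect)
            k_max = pc.get("k_max") or min(matrix.n_items - 1, 15)
            curve = prey.wgss_curve(matrix, dendro, k_max=k_max)
            k_auto, _, degenerate = prey.select_k_inflection(curve)
            k = k_auto if pc.get("k", "auto") == "auto" else int(pc["k"])
            cats = prey.cut_to_categories(dendro, k, names=pc.get("names"))
            mem_path = out / "prey_categories.csv"
            io.write_category_membership(cats, mem_path)
            (out / "prey_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            manifest.outputs += [str(mem_path), str(out / "prey_dendrogram.nwk")]
            report["prey"] = {
                "dialect": dialect,
                "k_selected": k_auto,
                "k_used": k,
                "degenerate": degenerate,
                "wgss": [[kk, round(w, 10)] for kk, w in curve],
                "membership": {c: sorted(cats.items_of(c)) for c in cats.categories},
            }
            manifest.stage_status["prey"] = "ok"
        except Exception as err:
            manifest.stage_status["prey"] = "error"
            manifest.stage_errors["prey"] = f"prey: {err}"
            log.error("prey stage failed: %s", err)
    else:
        manifest.stage_status["prey"] = "skipped"

    # ---- diet assignment ----
    dc = config.get("diet")
    if dc:
        try:
            if "records" in dc:
                if cats is None:
                    raise diet.DietValidationError(
                        "long-format records need a completed prey stage"
                    )
                records = io.read_diet_records(dc["records"]).filter_life_stage()
                raw = diet.aggregate_importances(
                    records, known_items=cats.membership
                )
                profiles = {
                    sp: diet.categorize_profile(p, cats) for sp, p in raw.items()
                }
                habitat = (
                    io.read_habitat(dc["habitat"]) if dc.get("habitat") else {}
                )
            else:
                src = dc.get("category_importance", "packaged")
                table = (
                    datasets.load_diet_importance()
                    if src == "packaged"
                    else pd.read_csv(src)
                )
                cat_cols = [
                    c for c in table.columns
                    if c not in ("species", "habitat", "synthetic_category",
                                 "coarse_category")
                ]
                profiles = {
                    str(r["species"]): diet.DietProfile(
                        species=str(r["species"]),
                        item_importance={},
                        category_importance={c: float(r[c]) for c in cat_cols},
                    )
                    for _, r in table.iterrows()
                }
                habitat = (
                    dict(zip(table["species"], table["habitat"]))
                    if "habitat" in table.columns else {}
                )
            totals: dict[str, float] = {}
            for p in profiles.values():
                for c, v in p.category_importance.items():
                    totals[c] = totals.get(c, 0.0) + v
            assignments = []
            for sp in sorted(profiles):
                a = diet.assign_primary_diet(
                    profiles[sp].category_importance,
                    species=sp,
                    tie_rule=dc.get("tie_rule", "rare"),
                    category_totals=totals,
                )
                assignments.append(
                    diet.CategoryAssignment(
                        species=a.species, category=a.category,
                        importance=a.importance, tie=a.tie,
                        habitat=habitat.get(sp),
                    )
                )
            focal = max(totals, key=lambda c: totals[c])
            summary = diet.concentration_summary(
                assignments, profiles, threshold=0.5, focal=focal
            )
            asn_path = out / "diet_assignments.csv"
            pd.DataFrame(
                [
                    {
                        "species": a.species, "category": a.category,
                        "importance": a.importance, "tie": a.tie,
                        "habitat": a.habitat,
                    }
                    for a in assignments
                ]
            ).to_csv(asn_path, index=False)
            manifest.outputs.append(str(asn_path))
            report["diet"] = {
                "tie_rule": dc.get("tie_rule", "rare"),
                "per_category": summary["per_category"],
                "n_species": summary["n_species"],
                "n_over_half": summary["n_over_threshold"],
                "below_half": summary["below_threshold"],
                "focal": focal,
                "focal_counts": {
                    str(k): v for k, v in summary["focal_counts"].items()
                },
            }
            manifest.stage_status["diet"] = "ok"
        except Exception as err:
            manifest.stage_status["diet"] = "error"
            manifest.stage_errors["diet"] = f"diet: {err}"
            log.error("diet stage failed: %s", err)
    else:
        manifest.stage_status["diet"] = "skipped"

    # ---- morphology ----
    mc = config.get("morphology")
    if mc:
        try:
            specimens = io.read_measurements(mc["measurements"])
            chars = morpho.characters_table(specimens)
            z_table = morpho.z_transform(chars)
            chars_path = out / "functional_characters.csv"
            chars.join(z_table, rsuffix="_z").to_csv(chars_path)
            manifest.outputs.append(str(chars_path))
            report["morphology"] = {
                "n_species": int(len(chars)),
                "characters": list(chars.columns),
            }
            manifest.stage_status["morphology"] = "ok"
        except Exception as err:
            manifest.stage_status["morphology"] = "error"
            manifest.stage_errors["morphology"] = f"morphology: {err}"
            log.error("morphology stage failed: %s", err)
    else:
        manifest.stage_status["morphology"] = "skipped"

    # ---- comparative ----
    cc = config.get("comparative")
    if cc:
        try:
            if z_table is None:
                raise comparative.ComparativeError(
                    "comparative stage needs a completed morphology stage"
                )
            if not cc.get("tree"):
                raise comparative.ComparativeError("no tree supplied")
            tree = trees.load_tree(cc["tree"])
            tree, dropped = trees.reconcile(tree, list(z_table.index))
            zt = z_table.drop(index=dropped)
            pca_res = comparative.pca(zt)
            retained_axes = [f"PC{j + 1}" for j in pca_res.retained] or ["PC1", "PC2"]
            pms = comparative.phylomorphospace(
                tree, pca_res.scores, axes=retained_axes
            )
            node_rows = [
                {"node": nid, **coords} for nid, coords in pms["nodes"].items()
            ]
            pms_path = out / "phylomorphospace_nodes.csv"
            pd.DataFrame(node_rows).to_csv(pms_path, index=False)
            manifest.outputs.append(str(pms_path))

            report_cmp: dict = {
                "variance_fractions": [round(float(v), 10)
                                       for v in pca_res.variance_fraction],
                "retained_axes": retained_axes,
            }
            groupings: dict[str, pd.Series] = {}
            if assignments is not None:
                gmap = {a.species: a.category for a in assignments}
                if set(zt.index) <= set(gmap):
                    groupings["synthetic"] = pd.Series(
                        {sp: gmap[sp] for sp in zt.index}
                    )
                hmap = {a.species: a.habitat for a in assignments}
                if all(hmap.get(sp) for sp in zt.index):
                    groupings["habitat"] = pd.Series(
                        {sp: hmap[sp] for sp in zt.index}
                    )
            wanted = cc.get("groupings")
            if wanted:
                groupings = {k: v for k, v in groupings.items() if k in wanted}
            nsim = int(cc.get("nsim", 1000))
            manova_out = {}
            asr_out = {}
            for name, gser in groupings.items():
                try:
                    res = comparative.phylo_manova(
                        tree, zt, gser, nsim=nsim, seed=seed
                    )
                    manova_out[name] = {
                        "wilks": round(res.wilks_observed, 10),
                        "p": res.p_value,
                        "nsim": res.nsim,
                        "seed": res.seed,
                        "group_sizes": res.group_sizes,
                    }
                except comparative.ComparativeError as err:
                    manova_out[name] = {"error": str(err)}
                asr = comparative.mk1_asr(tree, gser.to_dict())
                shifts = comparative.asr_transition_summary(asr)
                asr_out[name] = {
                    "rate": round(asr.rate, 10),
                    "log_likelihood": round(asr.log_likelihood, 10),
                    "n_transitions": len(shifts),
                    "transitions": [
                        {k: v for k, v in s.items()
                         if k in ("parent", "child", "from_state", "to_state")}
                        for s in shifts
                    ],
                }
            report_cmp["manova"] = manova_out
            report_cmp["asr"] = asr_out
            if "synthetic" in groupings:
                dfa = comparative.lda_classify(zt, groupings["synthetic"])
                conf_path = out / "dfa_confusion.csv"
                dfa.confusion.to_csv(conf_path)
                manifest.outputs.append(str(conf_path))
                report_cmp["dfa"] = {
                    "accuracy": round(dfa.accuracy, 10),
                    "mismatches": dfa.mismatches,
                }
            report["comparative"] = report_cmp
            manifest.stage_status["comparative"] = "ok"
        except Exception as err:
            manifest.stage_status["comparative"] = "error"
            manifest.stage_errors["comparative"] = f"comparative: {err}"
            log.error("comparative stage failed: %s", err)
    else:
        manifest.stage_status["comparative"] = "skipped"

    _dump_json(report, out / "report.json")
    manifest.outputs.append(str(out / "report.json"))
    _dump_json(manifest.to_dict(), out / "manifest.json")
    return report


def validate_inputs(paths: dict) -> list[dict]:
    """Cross-file consistency checks; returns a list of issue entries.

    Each entry has ``level`` (error/warning), ``file`` and ``message``.
    Never raises: callers decide what is fatal.
    """
    issues: list[dict] = []

    def note(level, file, message):
        issues.append({"level": level, "file": str(file), "message": message})

    matrix = None
    if paths.get("traits"):
        try:
            matrix = io.read_prey_traits(paths["traits"])
        except Exception as err:
            note("error", paths["traits"], str(err))

    species_sets: dict[str, set[str]] = {}
    if paths.get("records"):
        try:
            rec = io.read_diet_records(paths["records"])
            species_sets["diet"] = set(rec.species())
            if matrix is not None:
                bad = {r.prey_item for r in rec.records} - set(matrix.items)
                if bad:
                    note("error", paths["records"],
                         f"prey items not in trait matrix: {sorted(bad)}")
        except Exception as err:
            note("error", paths["records"], str(err))
    if paths.get("measurements"):
        try:
            specimens = io.read_measurements(paths["measurements"])
            species_sets["morphology"] = {m.species for m in specimens}
        except Exception as err:
            note("error", paths["measurements"], str(err))
    if paths.get("habitat"):
        try:
            species_sets["habitat"] = set(io.read_habitat(paths["habitat"]))
        except Exception as err:
            note("error", paths["habitat"], str(err))
    if paths.get("tree"):
        try:
            tree = trees.load_tree(paths["tree"])
            species_sets["tree"] = set(trees.tip_labels(tree))
        except Exception as err:
            note("error", paths["tree"], str(err))

    names = sorted(species_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            only_a = sorted(species_sets[a] - species_sets[b])
            only_b = sorted(species_sets[b] - species_sets[a])
            if only_a:
                note("warning", paths.get(a, a),
                     f"species in {a} absent from {b}: {only_a}")
            if only_b:
                note("warning", paths.get(b, b),
                     f"species in {b} absent from {a}: {only_b}")
    return issues
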