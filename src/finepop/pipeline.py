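"""End-to-end orchestration of the synthetic analysis flow.

``run_pipeline`` executes the stage order of the underlying study design —
simulate -> QC -> LD prune -> FST/PCA/RoH -> f-statistics -> paint ->
cluster/refine -> TVD -> NNLS -> dating — writing each stage's TSV
artifacts plus a JSON manifest (parameters, input hashes, package version)
into the output directory.  Stages are resumable: an artifact whose
recorded hash matches on disk is not recomputed; a corrupted intermediate
is detected by hash mismatch and rebuilt.

``make_demo`` generates the self-contained demonstration scenario: three
divergent sources, one recently admixed group (single pulse 13 generations
ago) and one older pair (19 generations), with truth tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ancestry, dating, finestructure, fstats, genio, painter, popstats, simdata


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # simulation block
    n_snps: int = 3000
    n_per_pop: int = 40
    n_admixed: int = 60
    fst_sources: float = 0.1
    admix_time_g: int = 13
    n_chrom: int = 3
    # stage parameters
    qc: dict = field(default_factory=dict)
    prune: dict = field(default_factory=lambda: {"r2_max": 0.4, "window_snps": 200, "step_snps": 25})
    paint: dict = field(default_factory=lambda: {"switch_rate": 50.0, "emission_error": 0.001})
    refine: dict = field(default_factory=lambda: {"threshold": 0.035, "max_pool": 3})
    # demo cohorts are small, so the size rule's member floor is relaxed
    refine_size: dict = field(
        default_factory=lambda: {"max_branch_clusters": 5, "min_cluster_individuals": 2}
    )
    nnls: dict = field(default_factory=dict)
    dating: dict = field(default_factory=lambda: {"bin_width_cm": 0.25, "d_min_cm": 0.5, "d_max_cm": 30.0})
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "qc", "prune", "popstats", "fstats",
            "paint", "cluster", "tvd", "nnls", "dating",
        ]
    )

    _KNOWN = {
        "out_dir", "seed", "n_snps", "n_per_pop", "n_admixed", "fst_sources",
        "admix_time_g", "n_chrom", "qc", "prune", "paint", "refine",
        "refine_size", "nnls", "dating", "stages",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class StageFailure(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run configured stages; returns the manifest dict (also written to
    ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}
    if manifest_path.exists():
        try:
            manifest_old = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            manifest_old = {"stages": {}}
    else:
        manifest_old = {"stages": {}}

    def stale_artifacts(stage: str) -> list[str]:
        """Artifacts of a previous run whose on-disk hash no longer matches
        the manifest (corruption or manual edits); stages are deterministic
        under the seed, so recomputation restores them."""
        rec = manifest_old.get("stages", {}).get(stage)
        if not rec or manifest_old.get("config") != manifest["config"]:
            return []
        bad = []
        for rel, digest in rec.get("artifacts", {}).items():
            p = out / rel
            if not p.exists() or _sha256(p) != digest:
                bad.append(rel)
        return bad

    state: dict = {}

    def record(stage: str, files: list[Path], t0: float, stale: list[str]) -> None:
        manifest["stages"][stage] = {
            "artifacts": {str(p.relative_to(out)): _sha256(p) for p in files},
            "seconds": round(time.time() - t0, 3),
        }
        if stale:
            manifest["stages"][stage]["recomputed_stale"] = stale
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    # --- stage implementations -------------------------------------------
    def stage_simulate() -> list[Path]:
        cfg = simdata.SimConfig(
            n_sources=3,
            fst_per_source=(config.fst_sources,) * 3,
            n_snps=config.n_snps,
            n_per_pop=config.n_per_pop,
            chrom_length_morgans=1.0,
            n_chrom=config.n_chrom,
            admix_proportions=(0.5, 0.3, 0.2),
            admix_time_g=config.admix_time_g,
            n_admixed=config.n_admixed,
            seed=config.seed,
        )
        sc = simdata.simulate_scenario(cfg)
        panel = sc["source_panels"][0]
        for p in sc["source_panels"][1:]:
            panel = panel.concat_individuals(p)
        panel = panel.concat_individuals(sc["admixed_panel"])
        state["panel"] = panel
        state["scenario"] = sc
        G = panel.to_genotypes()
        state["G_raw"] = G
        genio.write_plink(G, str(out / "simulated"))
        truth = sc["truth"].to_frame(sc["admixed_panel"].sample_meta["id"].tolist())
        _write_tsv(truth, out / "truth_ancestry.tsv")
        return [out / "simulated.ped", out / "simulated.map", out / "truth_ancestry.tsv"]

    def stage_qc() -> list[Path]:
        th = genio.QCThresholds(**config.qc)
        G, report = genio.qc_filter(state["G_raw"], th)
        state["G"] = G
        _write_tsv(report, out / "qc_removals.tsv")
        return [out / "qc_removals.tsv"]

    def stage_prune() -> list[Path]:
        keep = genio.ld_prune(state["G"], **config.prune)
        mask = state["G"].snp_meta["id"].isin(keep).to_numpy()
        state["G_pruned"] = state["G"].take_snps(mask)
        _write_tsv(pd.DataFrame({"id": keep}), out / "pruned_keep.tsv")
        return [out / "pruned_keep.tsv"]

    def stage_popstats() -> list[Path]:
        G = state["G_pruned"]
        mat, _ = popstats.pairwise_fst_matrix(G)
        mat.to_csv(out / "fst_matrix.tsv", sep="\t", float_format="%.10g")
        scores, frac = popstats.pca_genotypes(G, n_components=4)
        pca = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])])
        pca.insert(0, "id", G.sample_meta["id"])
        _write_tsv(pca, out / "pca_scores.tsv")
        _write_tsv(pd.DataFrame({"component": np.arange(1, len(frac) + 1), "var_frac": frac}),
                   out / "pca_varfrac.tsv")
        segs = popstats.detect_roh(G, window_snps=min(100, G.n_snp // config.n_chrom or 1))
        _write_tsv(popstats.segments_to_frame(segs), out / "roh_segments.tsv")
        return [out / "fst_matrix.tsv", out / "pca_scores.tsv", out / "pca_varfrac.tsv",
                out / "roh_segments.tsv"]

    def stage_fstats() -> list[Path]:
        G = state["G"]
        ft = fstats.allele_freqs(G)
        pops = list(ft.freqs)
        results = []
        if len(pops) >= 4:
            results.append(fstats.f3(pops[0], pops[1], pops[-1], ft))
            results.append(fstats.f4(pops[0], pops[1], pops[2], pops[-1], ft))
        _write_tsv(fstats.results_to_frame(results), out / "fstats.tsv")
        return [out / "fstats.tsv"]

    def stage_paint() -> list[Path]:
        cfgp = painter.PainterConfig(**config.paint)
        M = painter.paint_all_vs_all(state["panel"], cfgp)
        state["coancestry"] = M
        M.chunk_counts.to_csv(out / "chunkcounts.tsv", sep="\t", float_format="%.10g")
        M.chunk_lengths_cm.to_csv(out / "chunklengths.tsv", sep="\t", float_format="%.10g")
        return [out / "chunkcounts.tsv", out / "chunklengths.tsv"]

    def stage_cluster() -> list[Path]:
        M = state["coancestry"]
        pops = state["panel"].sample_meta["population"]
        ident = {i: i for i in M.ids}
        vecs = painter.copying_vectors(M, ident, basis="counts")
        tree, assign = finestructure.build_tree(vecs, n_clusters=max(4, pops.nunique()))
        assign = finestructure.refine_tree_size(tree, assign, **config.refine_size)
        assign = finestructure.refine_tree_tvd(assign, vecs, **config.refine)
        state["vectors"] = vecs
        state["assignment"] = assign
        _write_tsv(assign.to_frame(), out / "clusters.tsv")
        (out / "cluster_tree.nwk").write_text(tree.to_newick())
        return [out / "clusters.tsv", out / "cluster_tree.nwk"]

    def stage_tvd() -> list[Path]:
        focal = state["panel"].sample_meta.loc[
            state["panel"].sample_meta["population"] == "ADMIX", "id"
        ].tolist()
        reports = finestructure.tvd_levels(
            {"counts": state["vectors"]}, state["assignment"], focal
        )
        frame = pd.concat([r.to_frame() for r in reports], ignore_index=True)
        _write_tsv(frame, out / "tvd_levels.tsv")
        return [out / "tvd_levels.tsv"]

    def stage_nnls() -> list[Path]:
        assign = state["assignment"]
        vecs = state["vectors"]
        pops = state["panel"].sample_meta.set_index("id")["population"]
        # pick as sources the clusters dominated by each source population
        sources = []
        for src in ("SRC0", "SRC1", "SRC2"):
            best, best_frac = None, 0.0
            for cl, members in assign.clusters.items():
                frac = np.mean([pops[m] == src for m in members])
                if frac > best_frac:
                    best, best_frac = cl, frac
            if best and best not in sources:
                sources.append(best)
        if len(sources) < 2:
            raise StageFailure("could not identify source clusters")
        profiles = ancestry.cluster_profiles(
            vecs, assign, {"panel": sources}, **config.nnls
        )
        _write_tsv(profiles["panel"], out / "nnls_profiles.tsv")
        return [out / "nnls_profiles.tsv"]

    def stage_dating() -> list[Path]:
        sc = state["scenario"]
        adm = sc["admixed_panel"].to_genotypes()
        f1 = sc["source_freqs"][0]
        f2 = sc["source_freqs"][1]
        curve = dating.weighted_ld_curve(adm, f1, f2, **config.dating)
        fit = dating.fit_exp_decay(curve)
        _write_tsv(curve.to_frame(), out / "weighted_ld_curve.tsv")
        _write_tsv(
            pd.DataFrame(
                [{
                    "amplitude": fit.amplitude, "c0": fit.c0,
                    "generations": fit.generations if fit.generations is not None else np.nan,
                    "rss": fit.rss, "converged": fit.converged,
                }]
            ),
            out / "admixture_date.tsv",
        )
        return [out / "weighted_ld_curve.tsv", out / "admixture_date.tsv"]

    impl = {
        "simulate": stage_simulate, "qc": stage_qc, "prune": stage_prune,
        "popstats": stage_popstats, "fstats": stage_fstats, "paint": stage_paint,
        "cluster": stage_cluster, "tvd": stage_tvd, "nnls": stage_nnls,
        "dating": stage_dating,
    }
    unknown = [s for s in config.stages if s not in impl]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for stage in config.stages:
        t0 = time.time()
        stale = stale_artifacts(stage)
        try:
            files = impl[stage]()
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise StageFailure(f"stage {stage!r} failed: {exc}") from exc
        record(stage, files, t0, stale)
        note = f" (recomputed stale: {','.join(stale)})" if stale else ""
        print(f"[finepop] stage={stage} wall={time.time() - t0:.2f}s "
              f"artifacts={len(files)}{note}")
    return manifest


def make_demo(seed: int, out_dir: str, n_snps: int = 3000, n_per_pop: int = 30,
              n_admixed: int = 40) -> dict:
    """Self-contained demo dataset: three sources; a recently admixed group
    (pulse 13 generations ago) and an older pair (19 generations)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed + 1)
    anc = rng.uniform(0.05, 0.95, size=n_snps)
    # continental-scale source divergence so haplotype painting separates
    # the donor groups cleanly at demo SNP counts
    freqs = simdata.simulate_source_freqs(anc, np.array([0.15, 0.15, 0.15]), rng)
    snp_meta = simdata.default_snp_meta(n_snps, 3, 1.0)
    panels = []
    for k in range(3):
        pan, _ = simdata.simulate_panel(
            freqs[k], n_per_pop, np.random.default_rng(seed + 2 + k), snp_meta, f"SRC{k}"
        )
        panels.append(pan)
    recent, truth_b = simdata.simulate_admixed(
        panels[:2], np.array([0.5, 0.5]), 13, n_admixed,
        np.random.default_rng(seed + 10), pop_label="KWB_LIKE")
    older1, truth_p = simdata.simulate_admixed(
        panels[:2], np.array([0.6, 0.4]), 19, n_admixed,
        np.random.default_rng(seed + 11), pop_label="KWP_LIKE")
    older2, truth_s = simdata.simulate_admixed(
        panels[1:], np.array([0.7, 0.3]), 19, n_admixed,
        np.random.default_rng(seed + 12), pop_label="KWS_LIKE")
    panel = panels[0]
    for p in [*panels[1:], recent, older1, older2]:
        panel = panel.concat_individuals(p)
    G = panel.to_genotypes()
    genio.write_plink(G, str(out / "demo"))
    genio.write_eigenstrat(G, str(out / "demo"))
    for name, pan, tr in [
        ("KWB_LIKE", recent, truth_b), ("KWP_LIKE", older1, truth_p), ("KWS_LIKE", older2, truth_s)
    ]:
        _write_tsv(tr.to_frame(pan.sample_meta["id"].tolist()), out / f"truth_{name}.tsv")
    return {
        "panel": panel,
        "source_freqs": freqs,
        "groups": {"KWB_LIKE": (recent, truth_b), "KWP_LIKE": (older1, truth_p),
                   "KWS_LIKE": (older2, truth_s)},
    }
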