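"""End-to-end genome-survey orchestration on synthetic specimens.

``run_survey`` chains every stage the survey performs on a male/female
specimen pair: genome + read simulation, k-mer spectrum profiling of both
specimens, sex-system inference, SSR scanning, subtractive W-marker
discovery with in-silico PCR, and a mitogenome ANI/NJ analysis.  A single
root seed expands into fixed per-stage seeds so any stage can be re-run
reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

from .assemble import assembly_stats
from .kmer import SpectrumModel, count_kmers, infer_sex_system
from .mito import mito_feature_counts
from .phylo import ani_matrix, bootstrap_supports, p_distance, progressive_msa
from .simulate import (SimulationParams, simulate_mitogenome_set,
                       simulate_reads, simulate_survey_pair)
from .sexmarker import run_sexmarker
from .ssr import scan_sequences


class ConfigError(ValueError):
    pass


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome": {
        "female_is_zw": True,   # False = ZZ/ZZ null study (no W material)
        "length": 2_000_000,
        "gc": 0.3695,
        "heterozygosity_female": 0.0039,
        "heterozygosity_male": 0.0034,
        "repeat_fraction": 0.33,
        "ssr_density": 50.0,
        "w_segment_count": 10,
        "w_segment_lengths": [1000, 1500, 2000],
        # W-degeneration loss sized so the female haploid genome reads
        # ~1.5% smaller than the male's, the asymmetry scale seen in
        # heterogametic fish surveys
        "z_loss_bases": 77000,
        "coverage": 60.0,
        "error_rate": 0.0,
        "read_length": 150,
        "insert_size": 350,
        "insert_sigma": 30.0,
    },
    "kmer": {"k": 17, "min_depth": 5},
    "sexmarker": {"n_candidates": 50, "enabled": True},
    "mito": {"enabled": True, "n_taxa": 5, "subs_rate": 1.0,
             "bootstrap": 200, "ani": True},
}

# stage seeds are fixed offsets from the root seed (recorded in the report)
_STAGE_SEED_OFFSETS = {"genome": 0, "reads_male": 101, "reads_female": 102,
                       "sexmarker": 103, "mito": 104}


def _merge_config(user: dict | None) -> dict:
    def merge(default, given, path=""):
        if given is None:
            return json.loads(json.dumps(default))
        if not isinstance(given, dict) or not isinstance(default, dict):
            return given
        out = {}
        for key in given:
            if key not in default:
                raise ConfigError(f"unknown config key: {path + key}")
        for key, dval in default.items():
            if key in given and isinstance(dval, dict):
                out[key] = merge(dval, given[key], path + key + ".")
            elif key in given:
                out[key] = given[key]
            else:
                out[key] = json.loads(json.dumps(dval))
        return out

    return merge(DEFAULT_CONFIG, user)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def _stage_seed(root: int, stage: str) -> int:
    return (root * 1009 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_survey(config: dict | None = None, outdir=None, log=print) -> dict:
    """Run the full survey; returns the report dict (JSON-serializable).

    The report's ``content_hash`` covers everything except timestamps, so
    reruns with the same config hash identically.
    """
    cfg = _merge_config(config)
    root_seed = int(cfg["seed"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest: list[str] = []

    def stage(msg):
        log(f"[survey +{time.time() - t_start:7.1f}s] {msg}")

    g = cfg["genome"]
    if not g["female_is_zw"]:
        g = dict(g, w_segment_count=0, z_loss_bases=0,
                 heterozygosity_female=g["heterozygosity_male"])
    params_female = SimulationParams(
        genome_length=int(g["length"]), gc_target=float(g["gc"]),
        heterozygosity=float(g["heterozygosity_female"]),
        repeat_fraction=float(g["repeat_fraction"]),
        ssr_density=float(g["ssr_density"]),
        sex_system="ZW_female",
        w_segment_count=int(g["w_segment_count"]),
        w_segment_lengths=tuple(g["w_segment_lengths"]),
        z_loss_bases=int(g["z_loss_bases"]),
        read_length=int(g["read_length"]), insert_size=int(g["insert_size"]),
        insert_sigma=float(g["insert_sigma"]), coverage=float(g["coverage"]),
        error_rate=float(g["error_rate"]), seed=_stage_seed(root_seed, "genome"))

    stage("simulating male (ZZ) and female (ZW) genomes")
    male, female = simulate_survey_pair(
        params_female, male_heterozygosity=float(g["heterozygosity_male"]))

    stage("simulating paired-end reads")
    reads_male = simulate_reads(male, params_female,
                                seed=_stage_seed(root_seed, "reads_male"))
    reads_female = simulate_reads(female, params_female,
                                  seed=_stage_seed(root_seed, "reads_female"))

    stage("profiling k-mer spectra")
    k = int(cfg["kmer"]["k"])
    fits = {}
    for label, reads in (("male", reads_male), ("female", reads_female)):
        spec = count_kmers(reads, k)
        fit = SpectrumModel(spec, min_depth=int(cfg["kmer"]["min_depth"])).fit()
        fits[label] = fit
        if outdir is not None:
            spec.to_tsv(outdir / f"spectrum_{label}.tsv")
            manifest.append(f"spectrum_{label}.tsv")
    sex_system = infer_sex_system(fits["male"], fits["female"])
    stage(f"sex system call: {sex_system}")

    stage("scanning SSRs")
    ssr_blocks = {}
    for label, genome in (("male", male), ("female", female)):
        named = [(f"{label}_{h}", genome.sequence(h))
                 for h in genome.haplotype_names]
        records, summary = scan_sequences(named)
        st = assembly_stats([s for _n, s in named])
        ssr_blocks[label] = {"summary": dataclasses.asdict(summary),
                             "gc_percent": st.gc_percent}
        if outdir is not None:
            from .ssr import write_misa_tsv
            write_misa_tsv(outdir / f"ssr_{label}.tsv", records)
            manifest.append(f"ssr_{label}.tsv")

    marker_report = None
    if cfg["sexmarker"]["enabled"]:
        stage("subtractive W-marker discovery")
        male_ref = {f"male_{h}": male.sequence(h) for h in male.haplotype_names}
        female_ref = {f"female_{h}": female.sequence(h)
                      for h in female.haplotype_names}
        marker_dir = outdir / "sexmarker" if outdir is not None else None
        marker_report = run_sexmarker(
            reads_female, male_ref, female_ref,
            n_candidates=int(cfg["sexmarker"]["n_candidates"]),
            seed=_stage_seed(root_seed, "sexmarker"), outdir=marker_dir)
        if marker_dir is not None:
            manifest += [f"sexmarker/{n}" for n in
                         ("candidates.fasta", "candidates.bed", "primers.tsv",
                          "classification.tsv", "report.json")]

    mito_block = None
    if cfg["mito"]["enabled"]:
        m = cfg["mito"]
        stage("mitogenome simulation and phylogenetics")
        mitos = simulate_mitogenome_set(int(m["n_taxa"]), None,
                                        subs_rate=float(m["subs_rate"]),
                                        seed=_stage_seed(root_seed, "mito"))
        named = [(rec.name, rec.linearized_at_first_cds().sequence())
                 for rec in mitos]
        msa = progressive_msa(named)
        tree = bootstrap_supports(msa, replicates=int(m["bootstrap"]),
                                  seed=_stage_seed(root_seed, "mito"))
        mito_block = {
            "n_taxa": len(mitos),
            "lengths": [len(r) for r in mitos],
            "feature_counts": mito_feature_counts(mitos[0]),
            "newick": tree.to_newick(),
            "mean_p_distance": float(p_distance(msa).values.mean()),
        }
        if m["ani"]:
            labels, ani = ani_matrix(named)
            mito_block["ani_min"] = float(ani[ani < 100.0].min()) \
                if (ani < 100.0).any() else 100.0
            if outdir is not None:
                from .io import write_tsv
                write_tsv(outdir / "mito_ani.tsv", ["taxon"] + labels,
                          [[lab] + [f"{x:.3f}" for x in row]
                           for lab, row in zip(labels, ani)])
                manifest.append("mito_ani.tsv")
        if outdir is not None:
            (outdir / "mito_tree.nwk").write_text(tree.to_newick() + "\n")
            msa.to_fasta(outdir / "mito_msa.fasta")
            manifest += ["mito_tree.nwk", "mito_msa.fasta"]

    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    report = {
        "metadata": {"seed": root_seed, "config_hash": cfg_hash,
                     "stage_seeds": {s: _stage_seed(root_seed, s)
                                     for s in _STAGE_SEED_OFFSETS}},
        "spectrum_fits": {lab: fit.to_dict() for lab, fit in fits.items()},
        "sex_system": sex_system,
        "ssr": ssr_blocks,
        "sexmarker": marker_report,
        "mito": mito_block,
        "manifest": manifest,
    }
    report["content_hash"] = hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()).hexdigest()
    report["metadata"]["timestamps"] = {"started": t_start,
                                        "finished": time.time()}
    if outdir is not None:
        for rel in manifest:
            p = outdir / rel
            if not p.exists() or p.stat().st_size == 0:
                raise RuntimeError(f"missing or empty output file: {rel}")
        with open(outdir / "survey_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    stage("done")
    return report
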