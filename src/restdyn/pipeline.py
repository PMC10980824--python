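"""End-to-end orchestration: simulate -> behaviour -> envelope -> HMM ->
state metrics -> connectivity -> NBS -> group statistics.

``run_all`` executes the stages in dependency order into a run directory;
every output carries the configuration hash and seed, and a rerun with an
identical configuration is bit-identical.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, connectivity, envelope, group_stats, io, netstats, state_metrics, synthetic
from .config import RunConfig, WINDOW_SESSIONS
from .hmm import fit_hmm, viterbi_decode

log = logging.getLogger("restdyn")


def _setup_logging(run_dir: Path) -> None:
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)


def _stamp(run_dir: Path, config: RunConfig) -> None:
    (run_dir / "run_meta.json").write_text(
        json.dumps(
            {
                "config_hash": config.hash(),
                "seed": config.seed,
                "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                "schema_version": 1,
            },
            indent=1,
        )
    )


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline; returns a dict of headline outputs.

    Stages: (1) simulate envelope data + keypress streams, (2) behaviour
    indices, (3) standardize/concatenate/PCA, (4) HMM fit + Viterbi,
    (5) temporal parameters + power maps + state networks, (6) per-session
    connectomes + state-network strengths, (7) NBS induction contrast in
    the boost window, (8) mixed ANOVA on temporal parameters and Spearman
    correlations with behaviour.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    _stamp(run_dir, config)
    cfg = config.simulation
    results: dict = {"config_hash": config.hash()}

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s", name)

    try:
        stage("simulate")
        paths = synthetic.simulate_state_paths(cfg)
        dataset = synthetic.simulate_envelopes(paths, cfg)
        io.write_envelope_dataset(run_dir / "envelopes.h5", dataset, config_hash=config.hash())
        io.write_state_paths_json(run_dir / "true_state_paths.json", paths)

        stage("behaviour")
        block_tables = []
        for i, subj in enumerate(dataset.subjects):
            stream = synthetic.simulate_ftt_blocks(
                seed=int(np.random.SeedSequence(config.seed, spawn_key=(1, i)).generate_state(1)[0] % 2**31),
                learning_gain=0.5,
            )
            scored = behaviour.score_stream(stream)
            scored.insert(0, "subject", subj)
            block_tables.append(scored)
        blocks = behaviour.z_normalise(pd.concat(block_tables, ignore_index=True))
        indices = behaviour.subject_indices(blocks)
        blocks.to_csv(run_dir / "behaviour_blocks.csv", index=False)
        indices.to_csv(run_dir / "behaviour_indices.csv", index=False)

        stage("envelope")
        concat = envelope.standardize_concatenate(dataset)
        concat = envelope.prewhiten_pca(concat, n_components=config.n_pca_components)

        stage("hmm")
        model = fit_hmm(
            concat.Z,
            K=config.hmm.n_states,
            n_restarts=config.hmm.n_restarts,
            seed=config.seed,
            boundaries=concat.boundaries,
            covariance_type=config.hmm.covariance_type,
            rel_tol=config.hmm.rel_tol,
            max_iter=config.hmm.max_iter,
        )
        io.write_hmm_model(run_dir / "hmm_model.json", model, config_hash=config.hash())
        seq = viterbi_decode(model, concat.Z, boundaries=concat.boundaries)
        io.write_state_sequence(run_dir / "state_sequence.h5", seq)

        stage("states")
        tp = state_metrics.temporal_params_table(seq.split(), fs=cfg.fs, K=model.K)
        tp.to_csv(run_dir / "temporal_params.csv", index=False)
        maps = state_metrics.state_power_maps(seq.path, concat.X, K=model.K)
        pd.DataFrame(maps.T, columns=[f"state{k}" for k in range(model.K)]).to_csv(
            run_dir / "state_power_maps.tsv", sep="\t", index_label="node"
        )
        networks = {
            k: state_metrics.extract_state_network(maps[k], config.state_network_fraction).tolist()
            for k in range(model.K)
            if np.isfinite(maps[k]).any()
        }
        (run_dir / "state_networks.json").write_text(json.dumps(networks))

        stage("connectivity")
        matrices, powers = {}, {}
        for subj, sess, env in dataset.recordings():
            conn = connectivity.build_connectome(
                env, fs=cfg.fs, smooth_s=config.smooth_s, subject=subj, session=sess, band=config.band
            )
            matrices[(subj, sess)] = conn.matrix
            powers[(subj, sess)] = conn.power
        io.write_connectomes(
            run_dir / "connectomes.h5", matrices, powers, band=config.band, config_hash=config.hash()
        )
        strength_rows = [
            {
                "subject": subj,
                "session": sess,
                "state": k,
                "strength": connectivity.mean_connectivity_strength(matrices[(subj, sess)], nodes),
            }
            for (subj, sess) in matrices
            for k, nodes in networks.items()
            if len(nodes) >= 2
        ]
        pd.DataFrame(strength_rows).to_csv(run_dir / "state_network_strength.csv", index=False)

        stage("nbs")
        pre, post = WINDOW_SESSIONS["T1"]
        A = np.stack([matrices[(s, post)] for s in dataset.subjects])
        B = np.stack([matrices[(s, pre)] for s in dataset.subjects])
        nbs_res = netstats.nbs_fwer(
            (A, B),
            design="paired",
            threshold=config.nbs.threshold,
            n_perm=config.nbs.n_perm,
            seed=config.seed,
        )
        io.write_nbs_result(run_dir / "nbs_boost_induction.json", nbs_res)
        results["nbs_boost_components"] = len(nbs_res.components)
        results["nbs_boost_min_p"] = min(
            (c.p_fwer for c in nbs_res.components), default=float("nan")
        )

        stage("stats")
        half = len(dataset.subjects) // 2
        group_of = {
            s: ("Wake" if i < half else "Nap") for i, s in enumerate(dataset.subjects)
        }
        sess_design = [
            (w, ind, sess)
            for w, (pre_s, post_s) in WINDOW_SESSIONS.items()
            for ind, sess in (("pre", pre_s), ("post", post_s))
        ]
        anova_rows = []
        for _, row in tp.iterrows():
            for w, ind, sess in sess_design:
                if row["session"] == sess:
                    anova_rows.append(
                        {
                            "subject": row["subject"],
                            "group": group_of[row["subject"]],
                            "session": w,
                            "induction": ind,
                            "state": row["state"],
                            "FO": row["FO"],
                        }
                    )
        anova_df = pd.DataFrame(anova_rows)
        effects = []
        for k in sorted(anova_df["state"].unique()):
            sub = anova_df[anova_df["state"] == k].rename(columns={"FO": "value"})
            if sub["value"].isna().any():
                continue  # unvisited-state missingness: cell-wise exclusion
            res = group_stats.mixed_anova(sub)
            res.insert(0, "state", k)
            effects.append(res)
        anova_out = pd.concat(effects, ignore_index=True)
        anova_out["p_bonferroni"] = group_stats.bonferroni(
            anova_out["p_corrected"].to_numpy(), config.bonferroni_factor
        )
        anova_out.to_csv(run_dir / "anova_fo.csv", index=False)

        # Spearman: FO per state at baseline RS1 vs BMP
        corr_rows = []
        bmp = indices.set_index("subject")["bmp"]
        fo_rs1 = tp[tp["session"] == "RS1"].pivot(index="subject", columns="state", values="FO")
        for k in fo_rs1.columns:
            x = fo_rs1[k].reindex(bmp.index)
            ok = x.notna() & bmp.notna()
            if ok.sum() >= 5 and x[ok].std() > 0:
                sc = group_stats.spearman_ci(x[ok], bmp[ok])
                corr_rows.append({"state": k, "session": "RS1", **sc})
        corr = pd.DataFrame(corr_rows)
        if len(corr):
            corr["p_bonferroni"] = group_stats.bonferroni(
                corr["p"].to_numpy(), config.bonferroni_factor
            )
        corr.to_csv(run_dir / "spearman_fo_bmp.csv", index=False)

        results["n_states_fit"] = model.K
        results["hmm_score"] = model.score
        results["n_subjects"] = len(dataset.subjects)
        (run_dir / "results.json").write_text(json.dumps(results, indent=1))
        log.info("run complete")
        return results
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        log.error("stage %s failed: %s", current["stage"], exc)
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {exc}") from exc
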