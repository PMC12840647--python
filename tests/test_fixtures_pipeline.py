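"""Synthetic generator behaviour and end-to-end pipeline contracts."""

import json

import numpy as np
import pytest

from codonblosum import (
    CohortError,
    PipelineConfig,
    PipelineStageError,
    SubstitutionWeights,
    SyntheticSpec,
    enumerate_events,
    load_cds,
    make_cohort,
    make_toy_gene,
    neutral_summary,
    run_pipeline,
    tilt_probabilities,
)
from codonblosum.fixtures import make_domain_map_intervals


class TestToyGene:
    def test_deterministic_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        make_toy_gene(10, seed=1, fasta_path=p1)
        make_toy_gene(10, seed=1, fasta_path=p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert make_toy_gene(10, seed=2).cds != make_toy_gene(10, seed=1).cds

    def test_reloadable_and_stop_free(self, tmp_path):
        p = tmp_path / "g.fasta"
        gene = make_toy_gene(25, seed=3, fasta_path=p)
        reloaded = load_cds(p, gene.gene_id)
        assert reloaded.cds == gene.cds
        assert "*" not in gene.protein
        assert gene.codons[0] == "ATG"


class TestTilt:
    def test_beta_zero_is_neutral(self, toy_table):
        q = tilt_probabilities(toy_table, 0.0)
        assert np.allclose(q, toy_table.probs)

    def test_tilt_shifts_expected_score(self, toy_table):
        mu0, _ = neutral_summary(toy_table)
        q_cons = tilt_probabilities(toy_table, 1.0)
        q_rad = tilt_probabilities(toy_table, -1.0)
        assert q_cons @ toy_table.scores > mu0 > q_rad @ toy_table.scores

    def test_zero_prob_events_stay_zero(self, toy_gene):
        w = {p: 1.0 for p in SubstitutionWeights.uniform().w}
        w[("A", "G")] = 0.0
        table = enumerate_events(toy_gene, range(1, toy_gene.L + 1),
                                 SubstitutionWeights(w))
        q = tilt_probabilities(table, -2.0)
        assert np.all(q[table.probs == 0] == 0)
        assert q.sum() == pytest.approx(1.0)


class TestCohortGenerator:
    def test_deterministic(self, toy_gene):
        spec = SyntheticSpec(L=toy_gene.L, N=50, seed=5, selection_beta=-1.0)
        df1 = make_cohort(spec, toy_gene)
        df2 = make_cohort(spec, toy_gene)
        assert df1.equals(df2)

    def test_columns_and_classes(self, toy_gene):
        spec = SyntheticSpec(L=toy_gene.L, N=40, seed=6, nonsense_rate=0.3)
        df = make_cohort(spec, toy_gene)
        assert list(df.columns) == ["case_id", "gene", "protein_change", "variant_class"]
        assert set(df["variant_class"]) <= {"missense", "nonsense"}
        assert (df["variant_class"] == "missense").sum() == 40
        assert (df["variant_class"] == "nonsense").sum() > 0

    @pytest.mark.parametrize("beta,side", [(-2.0, "above"), (2.0, "below")])
    def test_direction_recovery(self, beta, side):
        """Tilted cohorts land on the correct side of the neutral radical
        fraction in >= 95% of seeded runs."""
        gene = make_toy_gene(120, seed=99)
        table = enumerate_events(gene, range(1, gene.L + 1),
                                 SubstitutionWeights.uniform())
        _, r_neutral = neutral_summary(table)
        radical = table.radical_flags.astype(float)
        hits = 0
        runs = 100
        for s in range(runs):
            spec = SyntheticSpec(L=gene.L, N=200, seed=7000 + s,
                                 selection_beta=beta, nonsense_rate=0.0)
            q = tilt_probabilities(table, beta)
            rng = np.random.default_rng(spec.seed)
            r_obs = radical[rng.choice(table.J, size=spec.N, p=q)].mean()
            if side == "above":
                hits += r_obs > r_neutral
            else:
                hits += r_obs < r_neutral
        assert hits >= 95


class TestPipeline:
    def _write_inputs(self, tmp_path, beta=-1.0, seed=11, L=80, N=60):
        gene = make_toy_gene(L, seed=seed, fasta_path=tmp_path / "g.fasta")
        spec = SyntheticSpec(L=L, N=N, seed=seed, selection_beta=beta)
        make_cohort(spec, gene, out_path=tmp_path / "m.tsv")
        dmap = tmp_path / "d.tsv"
        with open(dmap, "w") as fh:
            fh.write("gene_id\tdomain\tstart\tend\n")
            for name, s, e in make_domain_map_intervals(L):
                fh.write(f"{gene.gene_id}\t{name}\t{s}\t{e}\n")
        return PipelineConfig(
            fasta=str(tmp_path / "g.fasta"),
            maf=str(tmp_path / "m.tsv"),
            gene_id=gene.gene_id,
            domain_map=str(dmap),
            M=400,
            seed=seed,
        )

    def test_bundle_determinism(self, tmp_path):
        cfg = self._write_inputs(tmp_path)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(cfg, out_dir=out1)
        run_pipeline(cfg, out_dir=out2)
        for name in ("summary.tsv", "gof.tsv", "domains.tsv", "manifest.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_manifest_contents(self, tmp_path):
        cfg = self._write_inputs(tmp_path)
        result = run_pipeline(cfg, out_dir=tmp_path / "out")
        manifest = json.loads((tmp_path / "out" / "manifest.json").read_text())
        assert manifest["seed"] == cfg.seed and manifest["M"] == cfg.M
        assert manifest["N"] == result.summary.N
        assert "weights_digest" in manifest and "version" in manifest

    def test_zero_missense_fails_at_named_stage(self, tmp_path):
        gene = make_toy_gene(30, seed=2, fasta_path=tmp_path / "g.fasta")
        (tmp_path / "m.tsv").write_text(
            "case_id\tgene\tprotein_change\tvariant_class\n"
            f"c1\t{gene.gene_id}\tp.{gene.protein[4]}5*\tnonsense\n"
        )
        cfg = PipelineConfig(
            fasta=str(tmp_path / "g.fasta"),
            maf=str(tmp_path / "m.tsv"),
            gene_id=gene.gene_id,
            M=100,
            seed=1,
        )
        with pytest.raises(PipelineStageError, match="summarize") as exc:
            run_pipeline(cfg)
        assert isinstance(exc.value.cause, CohortError)

    def test_observed_vs_whole_cds_positions(self, tmp_path):
        cfg = self._write_inputs(tmp_path)
        r_obs = run_pipeline(cfg)
        import dataclasses

        r_all = run_pipeline(dataclasses.replace(cfg, positions_mode="whole-cds"))
        assert r_all.table.J >= r_obs.table.J
        assert r_obs.table.included_positions == {
            v.position for v in r_obs.cohort.missense
        }

    def test_radical_cohort_detected(self, tmp_path):
        cfg = self._write_inputs(tmp_path, beta=-2.0, N=150, seed=21)
        result = run_pipeline(cfg)
        assert result.test.p_rad < 0.05
        assert result.test.p_rad_opposite > 0.5

    def test_pipeline_uniformity_under_null(self):
        """Neutral cohorts through the full pipeline: rejection rate at
        nominal 0.05 stays inside the 99.9% band around the exact lattice
        null rate (the empirical p is super-uniform on a lattice)."""
        from scipy import stats

        from codonblosum import (
            DomainMap,
            build_cohort,
            p_values,
            parse_hgvsp,
            simulate,
            summarize,
        )

        gene = make_toy_gene(100, seed=31)
        weights = SubstitutionWeights.uniform()
        table = enumerate_events(gene, range(1, gene.L + 1), weights)
        _, rho = neutral_summary(table)
        N, M, trials, alpha = 50, 400, 200, 0.05
        radical = table.radical_flags.astype(float)

        rejections = 0
        rng = np.random.default_rng(12345)
        for t in range(trials):
            spec = SyntheticSpec(L=gene.L, N=N, seed=50_000 + t,
                                 selection_beta=0.0, nonsense_rate=0.0)
            df = make_cohort(spec, gene)
            parsed = [parse_hgvsp(lb, case_id=c, gene_id=gene.gene_id)
                      for c, lb in zip(df["case_id"], df["protein_change"])]
            cohort = build_cohort(gene, parsed)
            summary = summarize(cohort, DomainMap(gene_id=gene.gene_id, intervals=()))
            ev = enumerate_events(gene, {v.position for v in cohort.missense}, weights)
            reps = simulate(ev, N=summary.N, M=M, seed=int(rng.integers(2**31)))
            test = p_values(reps, summary.mean_score, summary.radical_fraction)
            rejections += test.p_rad <= alpha

        # exact lattice null rate: r_obs ~ Binomial(N, rho)/N approximately
        # (positions restriction makes this approximate; band is wide)
        k = np.arange(N + 1)
        surv = stats.binom.sf(k - 1, N, rho)  # P(R >= k/N)
        alpha_star = float(surv[surv <= alpha].max()) if np.any(surv <= alpha) else 0.0
        lo = stats.binom.ppf(0.0005, trials, max(alpha_star, 1e-6))
        hi = stats.binom.ppf(0.9995, trials, alpha)
        assert lo <= rejections <= max(hi, 1)

    def test_power_monotone_in_tilt_strength(self):
        """Detection power grows with |beta| (three-point check)."""
        gene = make_toy_gene(100, seed=41)
        weights = SubstitutionWeights.uniform()
        table = enumerate_events(gene, range(1, gene.L + 1), weights)
        radical = table.radical_flags.astype(float)
        scores = table.scores

        def power(beta, runs=60, N=100, M=300):
            q = tilt_probabilities(table, beta)
            hits = 0
            for s in range(runs):
                rng = np.random.default_rng(90_000 + s)
                obs = rng.choice(table.J, size=N, p=q)
                r_obs = radical[obs].mean()
                reps = rng.choice(table.J, size=(M, N), p=table.probs)
                r_s = radical[reps].mean(axis=1)
                hits += (r_s >= r_obs).mean() <= 0.05
            return hits / runs

        p_weak, p_mid, p_strong = power(-0.25), power(-0.75), power(-2.0)
        assert p_weak <= p_mid + 0.1  # allow MC wiggle at the soft end
        assert p_mid <= p_strong + 1e-9
        assert p_strong >= 0.95


class TestCli:
    def test_demo_and_test_subcommands(self, tmp_path):
        from click.testing import CliRunner

        from codonblosum.cli import main as cli_main

        runner = CliRunner()
        out = tmp_path / "demo"
        r = runner.invoke(
            cli_main,
            ["demo", "--seed", "7", "--beta", "-1.0", "-M", "300",
             "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        for f in ("gene.fasta", "cohort.tsv", "summary.tsv", "gof.tsv",
                  "domains.tsv", "manifest.json"):
            assert (out / f).exists()

        r2 = runner.invoke(
            cli_main,
            ["test", "--fasta", str(out / "gene.fasta"),
             "--maf", str(out / "cohort.tsv"), "--gene-id", "TOYGENE",
             "--domain-map", str(out / "domain_map.tsv"),
             "-M", "200", "--seed", "3", "--out-dir", str(tmp_path / "t")],
        )
        assert r2.exit_code == 0, r2.output
        assert "p_rad" in r2.output

    def test_seed_required_for_randomized_commands(self, tmp_path):
        from click.testing import CliRunner

        from codonblosum.cli import main as cli_main

        r = CliRunner().invoke(
            cli_main, ["simulate", "--out-dir", str(tmp_path)]
        )
        assert r.exit_code != 0
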