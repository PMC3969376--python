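"""Variable pruning, presence derivation, and the specialization index."""

import numpy as np
import pandas as pd
import pytest

import nichescan as ns


def env_frame(columns: dict) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns)
    df.insert(0, "site_id", [f"s{i}" for i in range(n)])
    return df


class TestPruneVariables:
    def test_perfect_correlation_forces_drop(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        env = env_frame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=30)})
        retained, report = ns.prune_variables(env, r_threshold=0.7)
        assert len(retained) == 2 and "c" in retained
        assert len(report) == 1

    def test_uncorrelated_noop(self):
        rng = np.random.default_rng(1)
        env = env_frame({k: rng.normal(size=200) for k in "abcd"})
        retained, report = ns.prune_variables(env, r_threshold=0.7)
        assert retained == list("abcd") and report.empty

    def test_planted_factor_recovery(self):
        # 15 independent factors plus 16 noisy copies (r ~ 0.9): pruning
        # keeps exactly one representative per factor group — with
        # empirical correlations the kept member of a factor/copy pair
        # is decided by sampling noise, so recovery is judged up to that
        # substitution
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            factors = rng.normal(size=(62, 15))
            cols = {f"f{i:02d}": factors[:, i] for i in range(15)}
            group = {f"f{i:02d}": i for i in range(15)}
            for j in range(16):
                src = j % 15
                cols[f"z{j:02d}"] = (0.9 * factors[:, src]
                                     + np.sqrt(1 - 0.81) * rng.normal(size=62))
                group[f"z{j:02d}"] = src
            retained, _ = ns.prune_variables(env_frame(cols), r_threshold=0.7)
            groups = sorted(group[v] for v in retained)
            if len(retained) == 15 and groups == list(range(15)):
                hits += 1
        assert hits >= 9

    def test_always_retains_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        env = env_frame({"a": x, "b": x + 1e-9, "c": -x})
        retained, _ = ns.prune_variables(env, r_threshold=0.5)
        assert len(retained) >= 1


class TestDerivePresence:
    def make_counts(self, july, nov):
        return pd.DataFrame({
            "species_id": ["sp"] * 2, "site_id": ["s1"] * 2,
            "season": ["july", "november"], "count": [july, nov]})

    @pytest.mark.parametrize("july,nov,expected", [
        (2, 0, 1),   # two in one season: present
        (1, 1, 0),   # never reaches two in a single season
        (0, 0, 0),
        (0, 5, 1),
    ])
    def test_min_count_rule(self, july, nov, expected):
        out = ns.derive_presence(self.make_counts(july, nov), min_count=2)
        assert out["present"].iloc[0] == expected

    def test_min_count_one_reading(self):
        out = ns.derive_presence(self.make_counts(1, 0), min_count=1)
        assert out["present"].iloc[0] == 1

    def test_missing_season_warns(self):
        counts = pd.DataFrame({"species_id": ["sp"], "site_id": ["s1"],
                               "season": ["july"], "count": [3]})
        with pytest.warns(UserWarning, match="season"):
            out = ns.derive_presence(counts)
        assert out["present"].iloc[0] == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ns.derive_presence(self.make_counts(-1, 0))


def presence_frame(species, site_ids, present_ids):
    return pd.DataFrame({
        "species_id": species, "site_id": site_ids,
        "present": [1 if s in present_ids else 0 for s in site_ids]})


class TestSpecializationIndex:
    def test_full_occupancy_gives_one(self):
        rng = np.random.default_rng(3)
        env = env_frame({"v": rng.normal(size=10)})
        pres = presence_frame("sp", env["site_id"], set(env["site_id"]))
        row = ns.specialization_index(env, pres, "v", "sp", n_rand=99, seed=0)
        assert row["S"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        env = env_frame({"v": [1, 2, 3, 4, 5]})
        pres = presence_frame("sp", env["site_id"], {"s1", "s2", "s3"})
        row = ns.specialization_index(env, pres, "v", "sp", n_rand=99, seed=0)
        # sigma_g = sqrt(2.5), sigma_s = 1
        assert row["S"] == pytest.approx(np.sqrt(2.5), abs=1e-12)

    def test_random_subsets_center_on_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=62)
        sg = x.std(ddof=1)
        vals = []
        for _ in range(999):
            idx = rng.choice(62, 15, replace=False)
            vals.append(sg / x[idx].std(ddof=1))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        env = env_frame({"v": rng.normal(size=30)})
        env2 = env.copy()
        env2["v"] = 3.7 * env2["v"] - 11.0
        occupied = set(env["site_id"][:8])
        pres = presence_frame("sp", env["site_id"], occupied)
        r1 = ns.specialization_index(env, pres, "v", "sp", n_rand=99, seed=1)
        r2 = ns.specialization_index(env2, pres, "v", "sp", n_rand=99, seed=1)
        assert r1["S"] == pytest.approx(r2["S"])
        assert r1["p_rand"] == r2["p_rand"]

    def test_constant_at_occupied_sites_sentinel(self):
        env = env_frame({"v": [1.0, 1.0, 1.0, 2.0, 3.0, 4.0]})
        pres = presence_frame("sp", env["site_id"], {"s0", "s1", "s2"})
        row = ns.specialization_index(env, pres, "v", "sp", n_rand=99, seed=0)
        assert np.isinf(row["S"])
        assert row["p_rand"] == pytest.approx(1 / 100)

    def test_constant_variable_skipped(self):
        env = env_frame({"v": [2.0] * 8})
        pres = presence_frame("sp", env["site_id"], set(env["site_id"][:4]))
        assert ns.specialization_index(env, pres, "v", "sp", n_rand=9, seed=0) is None

    def test_too_few_occupied_rejected(self):
        rng = np.random.default_rng(6)
        env = env_frame({"v": rng.normal(size=10)})
        pres = presence_frame("sp", env["site_id"], set(env["site_id"][:2]))
        with pytest.raises(ValueError, match="occupies"):
            ns.specialization_index(env, pres, "v", "sp", n_rand=9, seed=0)

    def test_p_uniform_under_random_occupancy(self):
        # fresh landscape per replicate keeps the p-values independent
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(200):
            x = rng.normal(size=40)
            env = env_frame({"v": x})
            occ = set(np.array(env["site_id"])[rng.choice(40, 10, replace=False)])
            pres = presence_frame("sp", env["site_id"], occ)
            row = ns.specialization_index(env, pres, "v", "sp", n_rand=99,
                                          seed=int(rng.integers(2**31)))
            ps.append(row["p_rand"])
        # one-tailed rejection at 0.05 near nominal
        rate = np.mean(np.asarray(ps) <= 0.05)
        assert 0.01 <= rate <= 0.10

    def test_narrow_niches_raise_s_monotonically(self):
        widths = [0.3, 0.6, 1.2]
        med = {}
        for w in widths:
            vals = []
            for rep in range(20):
                sites = ns.generate_sites(
                    ns.LandscapeSpec(n_sites=62, n_variables=2, seed=rep))
                x = sites["env01"]
                niche = ns.NicheSpec("sp", "env01", niche_center=float(x.mean()),
                                     niche_width=w, baseline_occupancy=0.9)
                pres = ns.generate_presence(sites, [niche], seed=rep)
                if pres["present"].sum() < 3:
                    continue
                row = ns.specialization_index(sites, pres, "env01", "sp",
                                              n_rand=9, seed=rep)
                vals.append(row["S"])
            med[w] = np.median(vals)
        assert med[0.3] > med[0.6] > med[1.2]

    def test_limiting_variable_attains_top_s(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            sites = ns.generate_sites(
                ns.LandscapeSpec(n_sites=62, n_variables=6, seed=300 + rep))
            x = sites["env03"]
            niche = ns.NicheSpec("sp", "env03", niche_center=float(x.mean()),
                                 niche_width=0.5, baseline_occupancy=0.8)
            pres = ns.generate_presence(sites, [niche], seed=300 + rep)
            if pres["present"].sum() < 3:
                continue
            table = ns.specialization_table(
                sites, pres, [f"env{i+1:02d}" for i in range(6)],
                n_rand=9, seed=rep)
            top = table.loc[table["S"].idxmax(), "variable"]
            hits += top == "env03"
        assert hits / n_rep >= 0.8
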