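import random

import pytest

from mirddr.formats import revcomp
from mirddr.target_scan import (
    ScanParams,
    collapse_to_genes,
    scan,
    site_expectation,
    targets_per_mirna_histogram,
)

MIRNA = "TGAAGCTGCCAGCATGATCTA"  # 21 nt


def _site_with(mirna, changes):
    """Perfect complementary site with target-side base substitutions given as
    {miRNA position (1-based): target base}."""
    site = list(revcomp(mirna))
    L = len(mirna)
    for pos, base in changes.items():
        site[L - pos] = base
    return "".join(site)


class TestSiteExpectation:
    def test_perfect_complement_scores_zero(self):
        e, mm, gu, gap = site_expectation(MIRNA, revcomp(MIRNA))
        assert (e, mm, gu, gap) == (0.0, 0, 0, 0)

    def test_seed_gu_doubled(self):
        # miRNA position 5 is G; target U opposite it is a wobble: 0.5 x 2
        assert MIRNA[4] == "G"
        site = _site_with(MIRNA, {5: "T"})
        e, mm, gu, gap = site_expectation(MIRNA, site)
        assert (e, gu) == (1.0, 1)

    def test_tail_mismatch_plus_tail_gu(self):
        # position 15 mismatch (1.0) + position 20 G:U (0.5), both unweighted
        assert MIRNA[19] == "T"
        site = _site_with(MIRNA, {15: _mismatch_base(MIRNA[14]), 20: "G"})
        e, mm, gu, gap = site_expectation(MIRNA, site)
        assert e == 1.5 and mm == 1 and gu == 1

    def test_seed_mismatch_doubled(self):
        site = _site_with(MIRNA, {5: _mismatch_base(MIRNA[4])})
        e, mm, _, _ = site_expectation(MIRNA, site)
        assert e == 2.0 and mm == 1

    def test_monotone_in_mismatches(self):
        site0 = revcomp(MIRNA)
        prev = 0.0
        for n_changes in (1, 2, 3):
            changes = {14 + i: _mismatch_base(MIRNA[13 + i]) for i in range(n_changes)}
            e, *_ = site_expectation(MIRNA, _site_with(MIRNA, changes))
            assert e > prev
            prev = e


def _mismatch_base(mirna_base: str) -> str:
    """Target base that neither pairs nor wobbles with the miRNA base."""
    return {"A": "C", "C": "A", "G": "G", "T": "T"}[mirna_base]


def oracle_scan(mirna: str, tx: str, params: ScanParams):
    """Independent exhaustive enumeration: every window, every gap placement,
    scored directly off the duplex definition."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(mirna)
    results = []
    for start in range(len(tx)):
        best = None
        geometries = [(L, None)]
        if params.max_gaps >= 1:
            geometries += [(L - 1, ("mirna", k)) for k in range(1, L - 1)]
            geometries += [(L + 1, ("site", k)) for k in range(1, L)]
        for width, gap in geometries:
            if start + width > len(tx):
                continue
            site = tx[start : start + width]
            e = 0.0
            states = []
            for mi in range(L):
                pos1 = mi + 1
                w = 2.0 if 2 <= pos1 <= 13 else 1.0
                if gap == ("mirna", mi):
                    e += 2.0 * w
                    states.append("bad")
                    continue
                if gap is not None and gap[0] == "mirna":
                    s_idx = width - 1 - (mi - 1) if mi > gap[1] else width - 1 - mi
                elif gap is not None and gap[0] == "site":
                    if mi == gap[1]:
                        e += 2.0 * w  # the extra site base
                    s_idx = width - 1 - (mi + 1) if mi >= gap[1] else width - 1 - mi
                else:
                    s_idx = width - 1 - mi
                m, t = mirna[mi], site[s_idx]
                if comp[m] == t:
                    states.append("ok")
                elif (m == "G" and t == "T") or (m == "T" and t == "G"):
                    e += 0.5 * w
                    states.append("bad")
                else:
                    e += 1.0 * w
                    states.append("bad")
            if e > params.max_expectation:
                continue
            if params.schwab:
                bad = [s == "bad" for s in states]
                if any(bad[9:11]) or sum(bad[1:12]) > 1:
                    continue
                run = best_run = 0
                for b in bad:
                    run = run + 1 if b else 0
                    best_run = max(best_run, run)
                if best_run > 2:
                    continue
            if best is None or e < best:
                best = e
        if best is not None:
            results.append((start, best))
    return results


class TestScan:
    def test_planted_perfect_site_found_exactly(self, default_sim):
        refs = default_sim.refs
        for name, tx, kind in default_sim.truth.target_sites:
            if kind != "perfect":
                continue
            sites = scan(name, refs.mirna_mature[name], {tx: refs.transcripts[tx]})
            assert any(s.expectation == 0.0 and s.site_start == 20 for s in sites), name

    def test_site_violating_cleavage_position_absent(self):
        site = _site_with(MIRNA, {10: _mismatch_base(MIRNA[9])})
        tx = {"t": "AAAC" + site + "GGTA"}
        hits = scan("m", MIRNA, tx, ScanParams(schwab=True))
        assert not any(s.site_start == 4 and s.n_mismatch == 1 for s in hits)
        # without the structural rules the site is reported
        hits = scan("m", MIRNA, tx, ScanParams(schwab=False))
        assert any(s.site_start == 4 for s in hits)

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = random.Random(9)
        params = ScanParams()
        for _ in range(12):
            mirna = "".join(rng.choice("ACGT") for _ in range(21))
            tx = "".join(rng.choice("ACGT") for _ in range(200))
            if rng.random() < 0.5:  # make hits likely in half the cases
                pos = rng.randrange(0, 170)
                tx = tx[:pos] + revcomp(mirna) + tx[pos + 21 :]
            ours = [(s.site_start, s.expectation) for s in scan("m", mirna, {"t": tx}, params)]
            assert ours == oracle_scan(mirna, tx, params)


class TestHistogram:
    def test_small_counts_in_first_bin(self):
        hist = targets_per_mirna_histogram({"m1": {"a", "b", "c"}})
        assert hist == {"1-20": 1}

    def test_zero_bin(self):
        hist = targets_per_mirna_histogram({"m1": set(), "m2": {"a"}})
        assert hist == {"0": 1, "1-20": 1}

    def test_totals_conserved(self):
        genes = {f"m{i}": {f"g{j}" for j in range(i * 7)} for i in range(9)}
        hist = targets_per_mirna_histogram(genes)
        assert sum(hist.values()) == len(genes)

    def test_gene_collapse_uses_map(self):
        from mirddr.target_scan import TargetSite

        sites = [
            TargetSite("m", "tx1", 0, 21, ("", "", ""), 0.0),
            TargetSite("m", "tx2", 0, 21, ("", "", ""), 0.0),
        ]
        collapsed = collapse_to_genes(sites, {"tx1": "g", "tx2": "g"})
        assert collapsed == {"m": {"g"}}
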