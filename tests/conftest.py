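import numpy as np
import pytest

from rohmap import GenotypeSite, ROHParams, ROHSegment, SimulationConfig


def roh_oracle(sites: list[GenotypeSite], params: ROHParams) -> list[ROHSegment]:
    """Brute-force ROH caller: enumerate every window and every candidate run
    and check all criteria directly.  Independent of the production path."""
    window = int(round(params.window_kb * 1000))
    max_gap = int(round(params.max_gap_kb * 1000))
    min_len = int(round(params.min_segment_kb * 1000))

    by_chrom: dict[str, list[GenotypeSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    def chrom_key(c: str):
        body = c[3:] if c.lower().startswith("chr") else c
        return (0, int(body), "") if body.isdigit() else (1, 0, body)

    segments = []
    for chrom in sorted(by_chrom, key=chrom_key):
        grp = by_chrom[chrom]
        # dedup identical positions; het wins on conflict
        pos_to_het: dict[int, bool] = {}
        for s in grp:
            pos_to_het[s.pos] = pos_to_het.get(s.pos, False) or (s.genotype_class == "het")
        pos = sorted(pos_to_het)
        het = [pos_to_het[p] for p in pos]
        n = len(pos)

        def window_hom(j: int) -> bool:
            hets = sum(
                1 for k in range(n) if pos[j] <= pos[k] <= pos[j] + window - 1 and het[k]
            )
            return hets <= params.max_het_per_window

        support = []
        for s_i in range(n):
            covering = [j for j in range(n) if pos[j] <= pos[s_i] <= pos[j] + window - 1]
            n_hom = sum(1 for j in covering if window_hom(j))
            support.append(n_hom / len(covering) >= params.min_hom_window_fraction)

        def linked(a: int, b: int) -> bool:  # consecutive sites a,b stay in one run
            return support[a] and support[b] and pos[b] - pos[a] <= max_gap

        for i in range(n):
            for j in range(i, n):
                if not all(support[i : j + 1]):
                    continue
                if any(pos[k + 1] - pos[k] > max_gap for k in range(i, j)):
                    continue
                left_max = i == 0 or not linked(i - 1, i)
                right_max = j == n - 1 or not linked(j, j + 1)
                if not (left_max and right_max):
                    continue
                if pos[j] - pos[i] + 1 >= min_len and j - i + 1 >= params.min_sites:
                    segments.append(ROHSegment(chrom, pos[i], pos[j], j - i + 1))
    return segments


def random_roh_instance(rng: np.random.Generator, max_sites: int = 100):
    """A random ROH-calling instance with parameters scaled to its extent."""
    n = int(rng.integers(1, max_sites + 1))
    span = int(rng.choice([2_000_000, 5_000_000, 10_000_000]))
    n_chroms = int(rng.integers(1, 3))
    sites = []
    for c in range(1, n_chroms + 1):
        m = n if n_chroms == 1 else int(rng.integers(1, n + 1))
        pos = np.sort(rng.choice(span, size=min(m, span), replace=False)) + 1
        het_p = float(rng.choice([0.05, 0.2, 0.5]))
        for p in pos:
            sites.append(
                GenotypeSite(
                    chrom=str(c),
                    pos=int(p),
                    genotype_class="het" if rng.random() < het_p else "hom",
                    coverage=30,
                )
            )
    params = ROHParams(
        window_kb=float(rng.choice([100, 500, 1000])),
        max_het_per_window=int(rng.integers(0, 3)),
        min_hom_window_fraction=float(rng.choice([0.05, 0.5, 1.0])),
        min_segment_kb=float(rng.choice([100, 500, 1000])),
        min_sites=int(rng.integers(1, 10)),
        max_gap_kb=float(rng.choice([100, 500, 1000])),
    )
    return sites, params


@pytest.fixture
def small_config() -> SimulationConfig:
    """A scaled-down generator configuration for fast unit tests."""
    return SimulationConfig(
        chromosome_lengths=(("1", 150_000_000), ("2", 120_000_000), ("3", 100_000_000)),
        n_coding_variants=3_000,
        site_density=15.0,
        seed=7,
    )
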