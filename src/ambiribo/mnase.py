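"""MNase cut-bias footprint null model.

Micrococcal nuclease cleaves more efficiently 5' of A and T than of C or G,
so footprint boundaries carry sequence bias that could in principle sculpt
coverage on its own.  This module fits an empirical cut-bias model from
observed footprints (base enrichment at the positions flanking each 5' and
3' cut, plus the footprint length distribution) and generates null
footprints from it: if cut bias alone explained an observed profile, the
null coverage generated on the actual sequence should correlate with the
observation much better than null coverage generated on a scrambled
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from ambiribo.ambigram import normalize_alphabet
from ambiribo.readquant import AlignmentSet
from ambiribo.riboprof import CoverageProfile

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

DEFAULT_N_FOOTPRINTS = 10_000
DEFAULT_RUNS = 10


@dataclass
class CutBiasModel:
    """Empirical nucleotide preferences flanking cut sites.

    ``five_prime_bias`` / ``three_prime_bias`` map flank offset -> per-base
    enrichment weight (observed frequency over reference background).  For
    a footprint [s, s+L): the 5' cut sits between s-1 and s (offsets -1,
    0), the 3' cut between s+L-1 and s+L (offsets -1, 0 relative to the
    cut).  ``length_dist`` is the empirical footprint length distribution.
    """

    five_prime_bias: dict[int, dict[str, float]]
    three_prime_bias: dict[int, dict[str, float]]
    length_dist: dict[int, float]

    def __post_init__(self) -> None:
        for biases in (self.five_prime_bias, self.three_prime_bias):
            for w in biases.values():
                if any(x < 0 for x in w.values()):
                    raise ValueError("bias weights must be non-negative")
        total = sum(self.length_dist.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError("length_dist must sum to 1")

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, biases in (
                ("five_prime", self.five_prime_bias),
                ("three_prime", self.three_prime_bias),
            ):
                for off, w in sorted(biases.items()):
                    for b in "ACGT":
                        fh.write(f"{name}\t{off}\t{b}\t{w[b]!r}\n")
            for L, p in sorted(self.length_dist.items()):
                fh.write(f"length\t{L}\t.\t{p!r}\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "CutBiasModel":
        five: dict[int, dict[str, float]] = {}
        three: dict[int, dict[str, float]] = {}
        lengths: dict[int, float] = {}
        with open(path) as fh:
            for line in fh:
                kind, key, base, val = line.rstrip("\n").split("\t")
                if kind == "length":
                    lengths[int(key)] = float(val)
                else:
                    target = five if kind == "five_prime" else three
                    target.setdefault(int(key), {})[base] = float(val)
        return cls(five, three, lengths)


def _base_frequencies(sequence: str) -> np.ndarray:
    seq = np.frombuffer(sequence.encode(), dtype="S1")
    freqs = np.array(
        [np.mean(seq == b.encode()) for b in "ACGT"], float
    )
    return freqs / freqs.sum()


def estimate_cut_bias(
    footprints: AlignmentSet,
    reference: str,
    min_footprints: int = 200,
    flank: int = 1,
) -> CutBiasModel:
    """Fit a CutBiasModel from observed footprints on a reference.

    For each cut, the bases at ``flank`` positions on either side are
    tabulated; empirical frequencies are divided by the reference base
    composition to give enrichment weights (1 = no preference).
    """
    if len(footprints) < min_footprints:
        raise ValueError(
            f"{len(footprints)} footprints < minimum {min_footprints}"
        )
    reference = normalize_alphabet(reference)
    background = _base_frequencies(reference)
    offsets = list(range(-flank, flank))  # e.g. [-1, 0] for flank=1

    def tabulate(cut_positions: np.ndarray) -> dict[int, dict[str, float]]:
        biases = {}
        for off in offsets:
            pos = cut_positions + off
            valid = (pos >= 0) & (pos < len(reference))
            counts = np.zeros(4)
            for p in pos[valid]:
                counts[_BASE_INDEX[reference[p]]] += 1
            freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
            biases[off] = {
                b: float(freqs[i] / background[i]) for b, i in _BASE_INDEX.items()
            }
        return biases

    starts = footprints.starts()
    ends = starts + footprints.lengths()
    lengths, counts = np.unique(footprints.lengths(), return_counts=True)
    length_dist = {int(L): float(c) / len(footprints) for L, c in zip(lengths, counts)}
    return CutBiasModel(tabulate(starts), tabulate(ends), length_dist)


def canonical_bias(
    bias: dict[int, dict[str, float]], reference: str
) -> dict[int, dict[str, float]]:
    """Rescale enrichment weights to the canonical form in which the
    background-weighted mean weight is 1 (the form `estimate_cut_bias`
    returns).  Weights are defined only up to a per-offset scale factor,
    so models must be brought to this form before being compared."""
    background = _base_frequencies(normalize_alphabet(reference))
    out = {}
    for off, w in bias.items():
        z = sum(background[i] * w[b] for b, i in _BASE_INDEX.items())
        out[off] = {b: w[b] / z for b in w}
    return out


def _position_weights(
    bias: dict[int, dict[str, float]], sequence: str
) -> np.ndarray:
    """Per-position product of flanking-base weights for a cut at each
    position (cut site between position-1 and position)."""
    L = len(sequence)
    codes = np.array([_BASE_INDEX.get(b, -1) for b in sequence])
    weights = np.ones(L + 1)
    for off, w in bias.items():
        wvec = np.array([w[b] for b in "ACGT"] + [1.0])  # unknown base -> 1
        pos = np.arange(L + 1) + off
        valid = (pos >= 0) & (pos < L)
        idx = np.where(valid, codes[np.clip(pos, 0, L - 1)], 4)
        weights *= wvec[idx]
    return weights


def sample_footprints(
    model: CutBiasModel,
    sequence: str,
    n: int = DEFAULT_N_FOOTPRINTS,
    seed: int = 0,
    reference: str = "null",
) -> AlignmentSet:
    """Draw ``n`` footprints from a cut-bias model on a sequence.

    Per footprint: a 5' cut position is drawn with probability proportional
    to the flanking-base weights along the sequence; the length is drawn
    from the model's length distribution re-weighted by the 3'-end base
    preference at the implied 3' cut.
    """
    from ambiribo.readquant import Read

    sequence = normalize_alphabet(sequence)
    L = len(sequence)
    lengths = np.array(sorted(model.length_dist))
    if L <= int(lengths.max()):
        raise ValueError("sequence shorter than the maximum footprint length")
    length_p = np.array([model.length_dist[int(x)] for x in lengths])
    w5 = _position_weights(model.five_prime_bias, sequence)[: L - int(lengths.max())]
    if not np.any(w5 > 0):
        raise ValueError("all-zero 5' weight landscape")
    p5 = w5 / w5.sum()
    w3 = _position_weights(model.three_prime_bias, sequence)
    rng = np.random.default_rng(seed)
    starts = rng.choice(len(p5), size=n, p=p5)
    # per-start length re-weighting by the 3' cut preference
    cut3 = starts[:, None] + lengths[None, :]
    lw = length_p[None, :] * w3[cut3]
    lw_sum = lw.sum(axis=1, keepdims=True)
    lw = np.where(lw_sum > 0, lw / lw_sum, length_p[None, :])
    cum = np.cumsum(lw, axis=1)
    drawn = lengths[(rng.random(n)[:, None] > cum).sum(axis=1)]
    reads = [Read(int(s), int(ln), "+") for s, ln in zip(starts, drawn)]
    return AlignmentSet(reference, L, reads)


def generate_null_footprints(
    model: CutBiasModel,
    sequence: str,
    n: int = DEFAULT_N_FOOTPRINTS,
    runs: int = DEFAULT_RUNS,
    seed: int = 0,
) -> list[CoverageProfile]:
    """Center-mapped null coverage from cut bias alone, one profile per
    run (default 10 runs of 10,000 footprints)."""
    sequence = normalize_alphabet(sequence)
    L = len(sequence)
    profiles = []
    for i in range(runs):
        fps = sample_footprints(model, sequence, n, seed=seed * runs + i)
        values = np.zeros(L)
        for r in fps.reads:
            values[r.start : r.start + r.length] += 1.0 / r.length
        profiles.append(
            CoverageProfile("null", "+", "center", values, normalized=False)
        )
    return profiles


@dataclass
class ModelComparison:
    r_actual: list[float]
    r_scrambled: list[float]
    tstat: float
    pvalue: float
    verdict: str
    undefined: bool = False


def scramble_sequence(sequence: str, seed: int = 0) -> str:
    """Uniform random permutation of the sequence (preserves composition)."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(normalize_alphabet(sequence)))
    rng.shuffle(chars)
    return "".join(chars)


def model_vs_observed(
    pred_profiles: list[CoverageProfile],
    observed: CoverageProfile | np.ndarray,
    scrambled_pred_profiles: list[CoverageProfile],
    low_r: float = 0.3,
    alpha: float = 0.05,
) -> ModelComparison:
    """Compare null-model coverage on the actual vs a scrambled sequence
    against the observed profile.

    Pearson correlation is computed per run; the two sets of run-level
    correlations are compared with Welch's t-test on Fisher-z transformed
    values.  Verdict "bias-insufficient" means no significant difference
    AND both correlation sets low: cut bias alone cannot explain the
    observed profile.
    """
    obs = observed.values if isinstance(observed, CoverageProfile) else np.asarray(observed, float)
    if np.std(obs) == 0:
        return ModelComparison([], [], math.nan, math.nan, "undefined", undefined=True)

    def correlations(profiles: list[CoverageProfile]) -> list[float]:
        out = []
        for p in profiles:
            v = p.values
            if len(v) != len(obs):
                raise ValueError("profiles must have equal length")
            if np.std(v) == 0:
                out.append(math.nan)
            else:
                out.append(float(stats.pearsonr(v, obs)[0]))
        return out

    r_act = correlations(pred_profiles)
    r_scr = correlations(scrambled_pred_profiles)
    z_act = np.arctanh(np.clip(r_act, -0.999999, 0.999999))
    z_scr = np.arctanh(np.clip(r_scr, -0.999999, 0.999999))
    tstat, pvalue = stats.ttest_ind(z_act, z_scr, equal_var=False)
    both_low = np.nanmean(r_act) < low_r and np.nanmean(r_scr) < low_r
    if pvalue >= alpha and both_low:
        verdict = "bias-insufficient"
    elif pvalue < alpha:
        verdict = "bias-distinguishable"
    else:
        verdict = "inconclusive"
    return ModelComparison(r_act, r_scr, float(tstat), float(pvalue), verdict)
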