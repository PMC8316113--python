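"""RNA secondary-structure and amino-acid context statistics.

Sliding-window minimum-free-energy (MFE) profiles locate structured
regions; the "local MFE peak" statistic (MFE_x minus the mean of MFE at
x +/- win/2) highlights positions *less* structured than their flanks;
footprint-boundary vectors (the discrete gradient of a coverage profile)
emphasize plateau edges.  Amino-acid context windows summarize the ~20
residues upstream of the approximate P-site, the stretch expected to
occupy the ribosome exit tunnel.

The folding engine is pluggable: any callable mapping a subsequence to a
scalar energy satisfies the contract.  The bundled default is a simplified
stacking-energy scorer (weighted Nussinov) adequate for relative profiles;
it does NOT reproduce RNAfold absolute energies.  When the ViennaRNA
Python bindings are installed, `vienna_engine` provides thermodynamic
folding at 28 degrees C (the insect-host temperature).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ambiribo.ambigram import normalize_alphabet

FoldingEngine = Callable[[str], float]

# base-pair stacking pseudo-energies (kcal/mol-like; lower = more stable)
_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}
_MIN_LOOP = 3

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}  # His neutral at cytoplasmic pH


def stacking_engine(seq: str) -> float:
    """Bundled simplified folding scorer: maximum-weight nested pairing
    (Nussinov recursion over stacking pseudo-energies, minimum loop 3).

    Returns 0 for unpairable sequences (e.g. homopolymers); an inverted
    repeat scores lower (more negative) than its shuffled counterpart.
    """
    s = normalize_alphabet(seq)
    n = len(s)
    if n < _MIN_LOOP + 2:
        return 0.0
    E = np.zeros((n, n))
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1, j]  # i unpaired
            pair = _PAIR_ENERGY.get((s[i], s[j]))
            if pair is not None:
                best = min(best, pair + E[i + 1, j - 1])
            for k in range(i + _MIN_LOOP + 1, j):
                pk = _PAIR_ENERGY.get((s[i], s[k]))
                if pk is not None:
                    best = min(best, pk + E[i + 1, k - 1] + E[k + 1, j])
            E[i, j] = best
    return float(E[0, n - 1])


def vienna_engine(seq: str, temperature: float = 28.0) -> float:
    """ViennaRNA MFE at the given temperature (requires the RNA bindings)."""
    import RNA

    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(seq.replace("T", "U"), md)
    _, mfe = fc.mfe()
    return float(mfe)


ENGINES: dict[str, FoldingEngine] = {"stacking": stacking_engine}
try:  # pragma: no cover - presence depends on the environment
    import RNA  # noqa: F401

    ENGINES["vienna"] = vienna_engine
except ImportError:
    pass


@dataclass
class MfeProfile:
    """Per-window MFE along a sequence; index i covers
    [i*step, i*step + window)."""

    window_size: int
    step: int
    mfe: np.ndarray

    def centers(self) -> np.ndarray:
        return np.arange(len(self.mfe)) * self.step + self.window_size / 2


def sliding_mfe(
    sequence: str,
    window: int = 50,
    step: int = 1,
    engine: FoldingEngine | str = "stacking",
) -> MfeProfile:
    """Minimum free energy along sliding windows of a sequence.

    Windows where the engine fails are flagged missing (NaN).
    """
    sequence = normalize_alphabet(sequence)
    if window > len(sequence):
        raise ValueError("window larger than the sequence")
    if isinstance(engine, str):
        engine = ENGINES[engine]
    n = (len(sequence) - window) // step + 1
    mfe = np.empty(n)
    for i in range(n):
        sub = sequence[i * step : i * step + window]
        try:
            mfe[i] = engine(sub)
        except Exception:
            mfe[i] = math.nan
    return MfeProfile(window, step, mfe)


def local_mfe_peak(profile: MfeProfile | np.ndarray, win: int) -> np.ndarray:
    """MFE_x - mean(MFE_{x-win/2}, MFE_{x+win/2}) at each interior
    position; edge positions (within win/2 of either end) are NaN.

    Positive values mark positions less structured than their flanks.
    The statistic is exactly linear in the profile.
    """
    if win % 2:
        raise ValueError("win must be even")
    v = profile.mfe if isinstance(profile, MfeProfile) else np.asarray(profile, float)
    h = win // 2
    out = np.full(len(v), math.nan)
    if h == 0:
        return np.zeros(len(v))
    if len(v) > 2 * h:
        out[h:-h] = v[h:-h] - 0.5 * (v[: -2 * h] + v[2 * h :])
    return out


def footprint_boundaries(values: np.ndarray) -> np.ndarray:
    """Discrete first derivative of a coverage profile (central differences
    interior, one-sided at the ends): steep changes mark plateau edges."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("profile must have length >= 2")
    return np.gradient(v)


@dataclass
class AaWindow:
    """Amino-acid context upstream of a footprint's anchor codon."""

    residues: str
    net_charge: int
    mean_hydrophobicity: float
    composition: dict[str, int]
    truncated: bool = False


def aa_context(
    footprint_start: int,
    footprint_length: int,
    orf: tuple[int, int],
    orf_translation: str,
    window: int = 20,
) -> AaWindow:
    """Context window for one footprint within an annotated ORF.

    The anchor codon contains the nucleotide at offset floor(2/3 * L) from
    the footprint's 5' end (the approximate P-site); the window holds up to
    ``window`` residues immediately upstream, truncated (and flagged) near
    the ORF start.
    """
    s, e = orf
    anchor_nt = footprint_start + (2 * footprint_length) // 3
    if not (s <= footprint_start and anchor_nt < e):
        raise ValueError("footprint (or its anchor) falls outside the ORF")
    anchor_codon = (anchor_nt - s) // 3
    lo = max(0, anchor_codon - window)
    residues = orf_translation[lo:anchor_codon]
    return AaWindow(
        residues=residues,
        net_charge=sum(_CHARGE.get(a, 0) for a in residues),
        mean_hydrophobicity=(
            float(np.mean([KYTE_DOOLITTLE[a] for a in residues if a in KYTE_DOOLITTLE]))
            if residues
            else math.nan
        ),
        composition=dict(Counter(residues)),
        truncated=len(residues) < window,
    )


@dataclass
class EnrichmentTest:
    amino_acid_pvalues: dict[str, float]
    charge_pvalue: float
    hydrophobicity_pvalue: float
    n_windows: int
    significant: bool


def aa_enrichment(
    windows: Sequence[AaWindow],
    orf_translation: str,
    n_permutations: int = 1000,
    window: int = 20,
    seed: int = 0,
    alpha: float = 0.05,
) -> EnrichmentTest:
    """Permutation test of cohort amino-acid context against the ORF
    background.

    The null redraws each cohort's anchor positions uniformly over the ORF
    and recomputes composition, mean net charge, and mean hydrophobicity;
    two-sided p-values compare the observed cohort to this null.
    """
    if not windows:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    n = len(windows)
    obs_charge = float(np.mean([w.net_charge for w in windows]))
    obs_hydro = float(np.nanmean([w.mean_hydrophobicity for w in windows]))
    obs_comp = Counter()
    total_res = 0
    for w in windows:
        obs_comp.update(w.composition)
        total_res += len(w.residues)
    aas = sorted(set(orf_translation) - {"*"})
    obs_frac = {a: obs_comp.get(a, 0) / total_res for a in aas}

    L = len(orf_translation)
    null_charge = np.empty(n_permutations)
    null_hydro = np.empty(n_permutations)
    null_frac = {a: np.empty(n_permutations) for a in aas}
    hydro_arr = np.array([KYTE_DOOLITTLE.get(a, np.nan) for a in orf_translation])
    charge_arr = np.array([_CHARGE.get(a, 0) for a in orf_translation])
    for i in range(n_permutations):
        anchors = rng.integers(window, L, size=n)
        charges = []
        hydros = []
        comp = Counter()
        tot = 0
        for a in anchors:
            lo = a - window
            charges.append(charge_arr[lo:a].sum())
            hydros.append(np.nanmean(hydro_arr[lo:a]))
            comp.update(orf_translation[lo:a])
            tot += window
        null_charge[i] = np.mean(charges)
        null_hydro[i] = np.nanmean(hydros)
        for a in aas:
            null_frac[a][i] = comp.get(a, 0) / tot

    def two_sided(null: np.ndarray, obs: float) -> float:
        centered = np.abs(null - null.mean())
        return float((np.sum(centered >= abs(obs - null.mean())) + 1) / (len(null) + 1))

    aa_p = {a: two_sided(null_frac[a], obs_frac[a]) for a in aas}
    charge_p = two_sided(null_charge, obs_charge)
    hydro_p = two_sided(null_hydro, obs_hydro)
    m = len(aas) + 2  # Bonferroni over all tested features
    significant = min(min(aa_p.values()), charge_p, hydro_p) < alpha / m
    return EnrichmentTest(aa_p, charge_p, hydro_p, n, significant)
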