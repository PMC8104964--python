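"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the study conditions the pipeline was built for:

- amplicon reads: loci of 200-500 bp with 1-3 Cas9 cut sites tiled within a
  200 bp window and >= 50 bp from the amplicon ends; indel spectra dominated
  by 1-2 bp deletions for single guides, plus spanning deletions between cut
  sites for multi-guide RNPs; an exponential per-bp observation bias
  over-representing short templates;
- calibration pools: five fragments (146/249/349/447/539 bp) mixed at
  random molar ratios across 11 pools and sequenced to finite depth under
  the same exponential bias;
- arrayed screens: four 96-well plates with 74 gene wells and 14 controls
  each (9 neutral, 2 non-targeting, 1 positive, 2 essential), column 12
  reserved for no-pulse and media-only wells, duplicate treatments,
  multiplicative (lognormal) measurement noise, per-plate effects, and
  planted knockout effects.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .genotyping import LocusSpec, OutcomeCategory
from .size_bias import (BiasModel, CalibrationPool, DEFAULT_POOL_LENGTHS,
                        DEFAULT_REFERENCE_LENGTH)
from . import screen as scr

BASES = np.array(list("ACGT"))

#: Default neutral-control genes: tissue-restricted, not expressed in
#: monocyte-derived dendritic cells.
NEUTRAL_GENES = ("CRX", "KCNV1", "TRHR", "LALBA", "RPE65", "F13B",
                 "OR2D2", "OR51T1", "TAS2R9")
NONTARGETING = ("NTC1", "NTC2")
POSITIVE_GENE = "TNF"
ESSENTIAL_GENES = ("U2AF2", "POLR2A")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, rng) -> str:
    return "".join(_rng(rng).choice(BASES, size=length))


def make_synthetic_locus(length: int, n_cut_sites: int, seed,
                         name: str = "locus") -> LocusSpec:
    """A random amplicon with 1-3 cut sites.

    Cut sites fall within a <= 200 bp window and keep >= 50 bp flanks to
    the amplicon ends (the primer-design rule the genotyping assay assumes).
    """
    if not 200 <= length <= 500:
        raise InputError("locus length must be within 200-500 bp")
    if not 1 <= n_cut_sites <= 3:
        raise InputError("need 1-3 cut sites")
    flank = 50
    if length - 2 * flank < 10 * n_cut_sites:
        raise InputError("locus too short to place cut sites with 50 bp flanks")
    rng = _rng(seed)
    seq = random_sequence(length, rng)
    window = min(200, length - 2 * flank)
    window_start = int(rng.integers(flank, length - flank - window + 1))
    sites = np.sort(rng.choice(np.arange(window_start, window_start + window),
                               size=n_cut_sites, replace=False))
    while len(sites) != len(set(sites)):  # pragma: no cover - replace=False
        sites = np.sort(rng.choice(window, size=n_cut_sites, replace=False))
    return LocusSpec(name, seq, tuple(int(s) for s in sites))


# ---------------------------------------------------------------------------
# Editing-outcome spectra and read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditSpectrum:
    """A mixture over editing-outcome templates.

    Templates are tuples: ``("wt",)``, ``("del", site_index, k)`` (k bp
    removed immediately left of the cut), ``("ins", site_index, k)``,
    ``("span", j1, j2)`` (deletion between cut sites j1 and j2), and
    ``("malformed",)`` (an off-target-like partial fragment).
    ``error_rate`` is a per-base substitution rate applied to every read.
    """

    templates: tuple[tuple, ...]
    probabilities: tuple[float, ...]
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.probabilities):
            raise InputError("templates and probabilities differ in length")
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InputError("probabilities must be >= 0 and sum to 1")
        if not 0 <= self.error_rate < 0.2:
            raise InputError("error_rate out of range")


def single_guide_spectrum(efficiency: float = 0.9,
                          error_rate: float = 0.0) -> EditSpectrum:
    """Default single-guide mixture: edits dominated by 1-2 bp deletions."""
    e = float(efficiency)
    if not 0 <= e <= 1:
        raise InputError("efficiency must be in [0, 1]")
    templates = [("wt",), ("del", 0, 1), ("del", 0, 2), ("ins", 0, 1),
                 ("del", 0, 4)]
    probs = [1 - e, 0.50 * e, 0.30 * e, 0.12 * e, 0.08 * e]
    return EditSpectrum(tuple(templates), tuple(probs), error_rate)


def multi_guide_spectrum(n_cut_sites: int, efficiency: float = 0.95,
                         error_rate: float = 0.0) -> EditSpectrum:
    """Default multi-guide mixture: spanning deletions plus small indels."""
    if n_cut_sites < 2:
        raise InputError("multi-guide spectrum needs >= 2 cut sites")
    e = float(efficiency)
    templates: list[tuple] = [("wt",)]
    probs = [1 - e]
    templates += [("span", 0, n_cut_sites - 1)]
    probs += [0.45 * e]
    per_site = 0.55 * e / n_cut_sites
    for j in range(n_cut_sites):
        templates += [("del", j, 1), ("del", j, 2)]
        probs += [0.6 * per_site, 0.4 * per_site]
    return EditSpectrum(tuple(templates), tuple(probs), error_rate)


def realize_template(template: tuple, locus: LocusSpec, rng) -> tuple[str, str]:
    """Materialise a template into (sequence, expected_category)."""
    ref = locus.reference_seq
    cuts = locus.cut_sites
    kind = template[0]
    if kind == "wt":
        return ref, OutcomeCategory.WILDTYPE.value
    if kind == "del":
        _, j, k = template
        c = cuts[j]
        return ref[:c - k] + ref[c:], OutcomeCategory.DELETION.value
    if kind == "ins":
        _, j, k = template
        c = cuts[j]
        ins = random_sequence(k, rng)
        return ref[:c] + ins + ref[c:], OutcomeCategory.INSERTION.value
    if kind == "span":
        _, j1, j2 = template
        if j1 >= j2:
            raise InputError("spanning template needs two distinct cut sites")
        return (ref[:cuts[j1]] + ref[cuts[j2]:],
                OutcomeCategory.SPANNING_DELETION.value)
    if kind == "malformed":
        # an off-target-like partial fragment: one boundary > 40 bp from
        # every cut site
        prefix_end = cuts[0] - 45
        suffix_start = cuts[-1] + 45
        if prefix_end >= len(ref) - suffix_start:
            frag = ref[:prefix_end]
        else:
            frag = ref[suffix_start:]
        if len(frag) < 30:
            raise InputError("locus too short to build a malformed fragment")
        return frag, OutcomeCategory.MALFORMED_LAYOUT.value
    raise InputError(f"unknown template kind {kind!r}")


def _add_substitutions(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def simulate_edited_reads(locus: LocusSpec, spectrum: EditSpectrum,
                          n_reads: int, bias: BiasModel, seed,
                          sample_name: str = "sample"
                          ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads from an outcome mixture under length-dependent bias.

    Template i with length l_i is observed with probability proportional to
    ``p_i * 2 ** (slope * (l_i - l_WT))``, so that the count correction
    inverts the bias in expectation. Returns ``(reads, truth)`` where reads
    are ``(read_id, sequence)`` pairs and the truth table records each
    template's mixture probability, biased observation weight and drawn
    count.
    """
    if n_reads <= 0:
        raise InputError("n_reads must be > 0")
    rng = _rng(seed)
    l_wt = locus.amplicon_length_wt

    seqs, cats = [], []
    for tmpl in spectrum.templates:
        s, cat = realize_template(tmpl, locus, rng)
        seqs.append(s)
        cats.append(cat)
    lengths = np.array([len(s) for s in seqs])
    p = np.asarray(spectrum.probabilities, dtype=float)
    weights = p * 2.0 ** (bias.slope_log2_per_bp * (lengths - l_wt))
    weights /= weights.sum()
    counts = rng.multinomial(n_reads, weights)

    reads: list[tuple[str, str]] = []
    idx = 0
    for tmpl, seq, count in zip(spectrum.templates, seqs, counts):
        for _ in range(count):
            reads.append((f"{sample_name}:{idx}",
                          _add_substitutions(seq, spectrum.error_rate, rng)))
            idx += 1
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    truth = pd.DataFrame({
        "template": [repr(t) for t in spectrum.templates],
        "category": cats,
        "length": lengths,
        "probability": p,
        "observation_weight": weights,
        "drawn_count": counts,
    })
    return reads, truth


# ---------------------------------------------------------------------------
# Calibration pools
# ---------------------------------------------------------------------------

def simulate_calibration_pools(lengths=DEFAULT_POOL_LENGTHS, n_pools: int = 11,
                               slope: float = None, depth: int | None = 1_000_000,
                               seed=None,
                               reference_length: int = DEFAULT_REFERENCE_LENGTH
                               ) -> list[CalibrationPool]:
    """Simulate spike-in pools sequenced under an exponential length bias.

    Starting molar fractions are Dirichlet-distributed per pool; observed
    fractions follow ``s_i * 2 ** (slope * (l_i - l_ref))`` renormalized,
    sampled multinomially at ``depth`` reads (or exactly, ``depth=None``).
    """
    from .size_bias import DEFAULT_SLOPE_LOG2_PER_BP
    if slope is None:
        slope = DEFAULT_SLOPE_LOG2_PER_BP
    lengths = tuple(int(l) for l in lengths)
    if len(lengths) < 2:
        raise InputError("need >= 2 fragment lengths")
    if reference_length in lengths:
        ref_idx = lengths.index(reference_length)
    else:
        ref_idx = int(np.argmin([abs(l - reference_length) for l in lengths]))
    rng = _rng(seed)
    arr = np.array(lengths, dtype=float)
    pools = []
    for k in range(n_pools):
        s = rng.dirichlet(np.full(len(lengths), 2.0))
        w = s * 2.0 ** (slope * (arr - arr[ref_idx]))
        w /= w.sum()
        if depth is None:
            m = w
        else:
            if depth <= 0:
                raise InputError("depth must be > 0")
            m = rng.multinomial(depth, w) / depth
        pools.append(CalibrationPool(lengths, tuple(s), tuple(m), ref_idx,
                                     pool_id=f"pool{k + 1:02d}"))
    return pools


# ---------------------------------------------------------------------------
# Arrayed screen
# ---------------------------------------------------------------------------

_ROWS = string.ascii_uppercase[:8]
_WELLS = [f"{r}{c}" for r in _ROWS for c in range(1, 13)]


@dataclass
class ScreenTruth:
    """Ground truth for a simulated screen.

    ``true_effects`` maps gene -> true log2 effect on the readout cytokine
    (neutral and non-targeting controls are 0 by construction; the positive
    control carries a strong negative effect). Noise SDs are in log2 units
    per individual measurement.
    """

    layout: pd.DataFrame
    true_effects: dict[str, float]
    plate_effects: dict[str, float]
    noise_sd_log2: float = 0.3
    luminescence_noise_sd_log2: float = 0.1
    baseline_absorbance: float = 1.2
    media_background: float = 0.08
    media_background_sd: float = 0.005
    luminescence_mean: float = 2.0e5
    luminescence_background: float = 500.0
    essential_viability_log2: float = -1.5
    n_treatment_replicates: int = 2
    assay: str = "TNFa"

    def to_dict(self) -> dict:
        return {
            "true_effects": self.true_effects,
            "plate_effects": self.plate_effects,
            "noise_sd_log2": self.noise_sd_log2,
            "luminescence_noise_sd_log2": self.luminescence_noise_sd_log2,
            "baseline_absorbance": self.baseline_absorbance,
            "media_background": self.media_background,
            "luminescence_mean": self.luminescence_mean,
            "n_treatment_replicates": self.n_treatment_replicates,
            "assay": self.assay,
        }


def make_screen_layout(seed, n_plates: int = 4,
                       n_gene_wells_per_plate: int = 74,
                       gene_names: list[str] | None = None) -> pd.DataFrame:
    """Randomised plate layouts following the study design.

    Each plate: column 12 reserved (4 no-pulse + 4 media-only wells), the 14
    controls in random positions, and the remaining positions filled with
    gene targets. With the defaults (4 plates x 74 gene wells = 296 well
    assignments over 291 unique genes) a few genes recur on more than one
    plate, as in a library where some genes carry extra wells.
    """
    rng = _rng(seed)
    n_gene_wells = n_plates * n_gene_wells_per_plate
    if gene_names is None:
        n_genes = max(1, n_gene_wells - 5)
        gene_names = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    assignments = list(gene_names)
    extra = n_gene_wells - len(assignments)
    if extra < 0:
        raise InputError("more gene names than gene wells")
    if extra:
        assignments += list(rng.choice(gene_names, size=extra, replace=False))
    assignments = [assignments[i] for i in rng.permutation(len(assignments))]

    rows = []
    ptr = 0
    for p in range(n_plates):
        plate = f"plate{p + 1}"
        col12 = [f"{r}12" for r in _ROWS]
        for w in col12[:4]:
            rows.append((plate, w, scr.NO_PULSE, ""))
        for w in col12[4:]:
            rows.append((plate, w, scr.MEDIA_ONLY, ""))
        avail = [w for w in _WELLS if not w.endswith("12")]
        controls = ([(scr.NEUTRAL_CONTROL, g) for g in NEUTRAL_GENES]
                    + [(scr.NONTARGETING_CONTROL, g) for g in NONTARGETING]
                    + [(scr.POSITIVE_CONTROL, POSITIVE_GENE)]
                    + [(scr.ESSENTIAL_CONTROL, g) for g in ESSENTIAL_GENES])
        n_needed = len(controls) + n_gene_wells_per_plate
        if n_needed > len(avail):
            raise InputError("plate cannot hold controls + gene wells")
        chosen = rng.choice(len(avail), size=n_needed, replace=False)
        chosen_wells = [avail[i] for i in chosen]
        for (role, gene), w in zip(controls, chosen_wells[:len(controls)]):
            rows.append((plate, w, role, gene))
        for w in chosen_wells[len(controls):]:
            rows.append((plate, w, scr.GENE_TARGET, assignments[ptr]))
            ptr += 1
        for w in set(avail) - set(chosen_wells):
            rows.append((plate, w, scr.EMPTY, ""))
    layout = pd.DataFrame(rows, columns=scr.LAYOUT_COLUMNS)
    return layout.sort_values(["plate", "well"], ignore_index=True)


def make_screen_truth(seed, layout: pd.DataFrame | None = None,
                      planted_effects: dict[str, float] | None = None,
                      positive_control_effect: float = -4.0,
                      plate_effect_range: tuple[float, float] = (0.8, 1.25),
                      **kwargs) -> ScreenTruth:
    """Assemble ground truth: layout, per-gene effects, plate multipliers."""
    rng = _rng(seed)
    if layout is None:
        layout = make_screen_layout(rng)
    effects = {g: 0.0 for g in layout.loc[layout["gene"] != "", "gene"]}
    effects[POSITIVE_GENE] = positive_control_effect
    if planted_effects:
        unknown = set(planted_effects) - set(effects)
        if unknown:
            raise InputError(f"planted effects for genes not in layout: "
                             f"{sorted(unknown)}")
        effects.update(planted_effects)
    lo, hi = plate_effect_range
    plates = sorted(set(layout["plate"]))
    plate_effects = {p: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                     for p in plates}
    return ScreenTruth(layout, effects, plate_effects, **kwargs)


def simulate_screen(truth: ScreenTruth, seed
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate measurement tables for one donor's plate set.

    Absorbance of a cell well:
    ``plate_effect * baseline * 2**effect * lognormal_noise + background``;
    luminescence is an independent lognormal around the cell-count mean
    (reduced for essential-gene wells), read twice per well. Media-only
    wells carry background only. Returns ``(layout, measurements,
    luminescence)`` in the tidy CSV schemas the scoring module consumes.
    """
    rng = _rng(seed)
    t = truth
    meas_rows, lum_rows = [], []
    for row in t.layout.itertuples(index=False):
        plate, well, role, gene = row.plate, row.well, row.role, row.gene
        if role == scr.EMPTY:
            continue
        pe = t.plate_effects[plate]
        if role == scr.MEDIA_ONLY:
            for rep in range(1, t.n_treatment_replicates + 1):
                bg = t.media_background + rng.normal(0, t.media_background_sd)
                meas_rows.append((plate, well, t.assay, rep, max(bg, 0.0)))
            for rep in (1, 2):
                lum = t.luminescence_background * 2.0 ** rng.normal(
                    0, t.luminescence_noise_sd_log2)
                lum_rows.append((plate, well, rep, lum))
            continue

        effect = 0.0 if role == scr.NO_PULSE else t.true_effects.get(gene, 0.0)
        viability = (t.essential_viability_log2
                     if role == scr.ESSENTIAL_CONTROL else 0.0)
        cell_count = t.luminescence_mean * 2.0 ** (
            viability + rng.normal(0, t.luminescence_noise_sd_log2))
        for rep in (1, 2):
            lum = cell_count * 2.0 ** rng.normal(
                0, t.luminescence_noise_sd_log2)
            lum_rows.append((plate, well, rep, lum + t.luminescence_background))
        secretion_per_cell = (pe * t.baseline_absorbance * 2.0 ** effect
                              * (cell_count / t.luminescence_mean))
        for rep in range(1, t.n_treatment_replicates + 1):
            noise = 2.0 ** rng.normal(0, t.noise_sd_log2)
            bg = t.media_background + rng.normal(0, t.media_background_sd)
            meas_rows.append((plate, well, t.assay, rep,
                              secretion_per_cell * noise + bg))

    measurements = pd.DataFrame(meas_rows, columns=scr.MEASUREMENT_COLUMNS)
    luminescence = pd.DataFrame(lum_rows, columns=scr.LUMINESCENCE_COLUMNS)
    return t.layout.copy(), measurements, luminescence
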