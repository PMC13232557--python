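"""Ground-truth liposome populations and synthetic amplicon reads.

Gene-expressing liposomes ("synthetic cells") are modelled as spherical
vesicles sitting in one focal plane of a 128 x 128 um field of view (FOV).
Each liposome carries one genotype (the DNA template it encapsulated), an
expression flag (in clonal samples only 40-80% of vesicles express their
gene), a diameter drawn from a truncated log-normal, and a localization /
dynamics state for the fluorescent reporter it produces:

* ``static_lumen``     -- reporter uniformly in the lumen (no membrane binding)
* ``static_membrane``  -- reporter stably bound to the membrane
* ``pulsing``          -- whole-membrane binding that switches on/off
* ``pole_to_pole``     -- a membrane cap that flips sides every half period
* ``circling``         -- a membrane cap rotating around the vesicle
* ``halted``           -- a cap frozen in place (a stalled oscillation)

Oscillation periods are drawn uniformly from 15-45 s, matching Min-system
dynamics in liposomes.  Centers drift by Brownian motion with a default
scale calibrated so the mean planar displacement over 10 s is 0.5 um.

The same module synthesizes amplicon sequencing reads: full-length
(default 1398 bp) amplicons with a 6-nt variant window (two mutated codons
of a membrane targeting sequence), substitution errors, read-length jitter
and a configurable fraction of off-length junk reads.
"""

from __future__ import annotations

import csv
import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, InputError, PlacementError

__all__ = [
    "PHENOTYPES",
    "OSC_MODES",
    "OSCILLATORY_MODES",
    "GenotypeSpec",
    "PopulationConfig",
    "OscillationState",
    "LiposomeState",
    "sample_population",
    "assign_oscillation",
    "membrane_fraction",
    "brownian_step",
    "default_mode_weights",
    "MtsLibrary",
    "make_mts_library",
    "generate_reads",
    "write_fastq",
    "population_to_csv",
]

PHENOTYPES = ("none", "lumen", "membrane", "oscillatory")
OSC_MODES = ("static_membrane", "static_lumen", "pulsing", "pole_to_pole", "circling", "halted")
#: Modes that carry a period/phase (time-varying membrane binding).
OSCILLATORY_MODES = ("pulsing", "pole_to_pole", "circling")

#: Per-axis Brownian scale (um * s^-1/2) such that the mean planar
#: displacement over 10 s equals 0.5 um: the planar displacement is
#: Rayleigh(s * sqrt(dt)) with mean s*sqrt(dt)*sqrt(pi/2), so
#: s = 0.5 / (sqrt(10) * sqrt(pi/2)) = 0.1262 um s^-1/2.
DEFAULT_DIFFUSION_SCALE = 0.5 / (math.sqrt(10.0) * math.sqrt(math.pi / 2.0))

#: Angular width (rad) of the Gaussian membrane cap used by the polar modes.
CAP_SIGMA_RAD = 0.5


@dataclass(frozen=True)
class GenotypeSpec:
    """One DNA template in the library.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"YFP"`` or ``"Var7"``.
    phenotype : str
        Reporter localization produced when the gene is expressed; one of
        ``none`` (no fluorescent product), ``lumen``, ``membrane`` or
        ``oscillatory``.
    amplicon_length : int
        Length of the PCR amplicon carrying this template (bp).
    mts_variant : str
        6-nt window (two codons) identifying the variant in sequencing
        reads, or ``""`` for genotypes without a variant window.
    template_share : float
        Relative template amount per unit volume of the clonal population.
    """

    name: str
    phenotype: str = "none"
    amplicon_length: int = 1398
    mts_variant: str = ""
    template_share: float = 1.0

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        if self.amplicon_length <= 0:
            raise ConfigurationError("amplicon_length must be positive")
        if len(self.mts_variant) not in (0, 6):
            raise ConfigurationError("mts_variant must be empty or 6 nt")


@dataclass
class PopulationConfig:
    """Composition and geometry of a simulated liposome sample.

    ``components`` pairs each genotype with the volume fraction of its
    clonal population in the final mix (fractions must sum to 1).  Every
    liposome expresses its gene independently with ``p_expression``
    (default 0.6, the midpoint of the 40-80% observed in clonal samples).
    Diameters follow a log-normal (median 8 um, sigma 0.45) truncated to
    2-20 um.
    """

    components: list[tuple[GenotypeSpec, float]]
    p_expression: float = 0.6
    diameter_lognormal: tuple[float, float] = (8.0, 0.45)
    diameter_range_um: tuple[float, float] = (2.0, 20.0)
    liposomes_per_fov: tuple[int, int] = (50, 120)
    n_fov: int = 1
    fov_um: float = 128.0
    min_gap_um: float = 1.0
    mode_weights: Mapping[str, float] | None = None
    seed: int | None = None

    def volume_fractions(self) -> np.ndarray:
        fr = np.asarray([f for _, f in self.components], dtype=float)
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"volume fractions sum to {fr.sum()!r}, not 1")
        if (fr < 0).any():
            raise ConfigurationError("volume fractions must be non-negative")
        return fr


@dataclass
class OscillationState:
    """Reporter localization dynamics of one liposome."""

    mode: str
    period_s: float | None = None
    phase: float = 0.0
    axis_angle: float = 0.0

    def __post_init__(self):
        if self.mode not in OSC_MODES:
            raise ConfigurationError(f"unknown oscillation mode {self.mode!r}")
        oscillatory = self.mode in OSCILLATORY_MODES
        if oscillatory and self.period_s is None:
            raise ConfigurationError(f"mode {self.mode!r} requires a period")
        if not oscillatory and self.period_s is not None:
            raise ConfigurationError(f"mode {self.mode!r} must not carry a period")
        self.phase = float(self.phase) % (2.0 * math.pi)


@dataclass
class LiposomeState:
    """Ground-truth record of one vesicle."""

    id: int
    genotype: GenotypeSpec
    center_um: tuple[float, float]
    diameter_um: float
    expressing: bool
    osc: OscillationState
    fov: int = 0
    pamcherry_basal: float = 1.0
    activated: bool = False
    diffusion_scale: float = DEFAULT_DIFFUSION_SCALE

    @property
    def radius_um(self) -> float:
        return 0.5 * self.diameter_um


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _sample_diameters(n, median, sigma, lo, hi, rng):
    """Truncated log-normal via rejection; every draw lands in [lo, hi]."""
    out = np.empty(n)
    filled = 0
    mu = math.log(median)
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled) + 16)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def default_mode_weights(phenotype: str) -> dict[str, float]:
    """Mode weights implied by a (expressed) phenotype.

    The relative abundance of the dynamic modes in real samples is not
    known; the oscillatory default splits weight evenly between the three
    time-varying modes with a small halted fraction.
    """
    if phenotype == "membrane":
        return {"static_membrane": 1.0}
    if phenotype == "oscillatory":
        return {"pulsing": 0.3, "pole_to_pole": 0.3, "circling": 0.3, "halted": 0.1}
    # 'lumen' and 'none' both render as lumen-localized (none is scaled to
    # zero by the expressing flag at render time).
    return {"static_lumen": 1.0}


def assign_oscillation(
    liposome: LiposomeState | None,
    mode_weights: Mapping[str, float],
    rng: np.random.Generator | int | None = None,
) -> OscillationState:
    """Draw a localization/dynamics state from a weight vector over modes.

    Oscillatory modes get a period uniform in [15, 45] s and a phase
    uniform in [0, 2*pi); a random cap axis is drawn for the polar modes.
    """
    rng = _as_rng(rng)
    modes = list(mode_weights.keys())
    w = np.asarray([mode_weights[m] for m in modes], dtype=float)
    for m in modes:
        if m not in OSC_MODES:
            raise ConfigurationError(f"unknown oscillation mode {m!r}")
    if (w < 0).any():
        raise ConfigurationError("mode weights must be non-negative")
    if w.sum() <= 0:
        raise ConfigurationError("mode weights must not all be zero")
    mode = modes[int(rng.choice(len(modes), p=w / w.sum()))]
    if mode in OSCILLATORY_MODES:
        return OscillationState(
            mode=mode,
            period_s=float(rng.uniform(15.0, 45.0)),
            phase=float(rng.uniform(0.0, 2.0 * math.pi)),
            axis_angle=float(rng.uniform(0.0, 2.0 * math.pi)),
        )
    return OscillationState(mode=mode, axis_angle=float(rng.uniform(0.0, 2.0 * math.pi)))


def _wrapped_gaussian_profile(center: float, sigma: float = CAP_SIGMA_RAD) -> Callable:
    """Angular weight function over [0, 2*pi), normalized to mean 1."""

    def profile(theta):
        theta = np.asarray(theta, dtype=float)
        d = np.angle(np.exp(1j * (theta - center)))
        w = np.exp(-0.5 * (d / sigma) ** 2)
        # mean of the wrapped gaussian over the circle
        norm = sigma * math.sqrt(2.0 * math.pi) / (2.0 * math.pi)
        return w / norm

    return profile


def _uniform_profile(theta):
    return np.ones_like(np.asarray(theta, dtype=float))


def membrane_fraction(osc: OscillationState, t: float) -> tuple[float, Callable]:
    """Membrane-bound reporter fraction and its angular weight profile at time ``t``.

    Returns ``(m, profile)`` where ``m`` is the fraction of reporter on the
    membrane (the remainder is uniform in the lumen) and ``profile`` maps
    angles in [0, 2*pi) to weights with circular mean 1.  Functional forms:
    static membrane binds at m=0.9 uniformly, static lumen at m=0.05;
    pulsing alternates 0.9/0.1 as a square wave; pole-to-pole keeps m=0.9
    with a Gaussian cap whose center flips by pi each half period; circling
    rotates the cap at 2*pi/period.
    """
    if t < 0:
        raise InputError("t must be >= 0")
    mode = osc.mode
    if mode == "static_membrane":
        return 0.9, _uniform_profile
    if mode == "static_lumen":
        return 0.05, _uniform_profile
    if mode == "halted":
        return 0.9, _wrapped_gaussian_profile(osc.axis_angle)
    frac = (t / osc.period_s + osc.phase / (2.0 * math.pi)) % 1.0
    if mode == "pulsing":
        return (0.9 if frac < 0.5 else 0.1), _uniform_profile
    if mode == "pole_to_pole":
        center = osc.axis_angle + (0.0 if frac < 0.5 else math.pi)
        return 0.9, _wrapped_gaussian_profile(center)
    if mode == "circling":
        center = osc.axis_angle + 2.0 * math.pi * frac
        return 0.9, _wrapped_gaussian_profile(center)
    raise ConfigurationError(f"unknown oscillation mode {mode!r}")


def brownian_step(
    center_um: tuple[float, float],
    dt_s: float,
    diffusion_scale: float,
    rng: np.random.Generator | int | None = None,
    fov_um: float = 128.0,
) -> tuple[float, float]:
    """Advance a liposome center by one Brownian increment.

    Per-axis Gaussian increments with standard deviation
    ``diffusion_scale * sqrt(dt)``, reflected at the FOV boundary.
    """
    if dt_s <= 0:
        raise InputError("dt must be positive")
    rng = _as_rng(rng)
    s = diffusion_scale * math.sqrt(dt_s)
    new = np.asarray(center_um, dtype=float) + rng.normal(0.0, s, size=2) if s > 0 else np.asarray(center_um, dtype=float)
    # reflect into [0, fov]
    new = np.abs(new)
    new = fov_um - np.abs(fov_um - new)
    return (float(new[0]), float(new[1]))


def _place_centers(radii, fov_um, min_gap_um, rng, max_attempts=5000):
    """Random sequential placement with pairwise spacing r_i + r_j + gap.

    Large vesicles are placed first (they are hardest to fit); each center
    stays at least its own radius away from the FOV edge so the vesicle is
    rendered in full.
    """
    order = np.argsort(radii)[::-1]
    n = len(radii)
    centers = np.full((n, 2), np.nan)
    placed_xy = np.empty((n, 2))
    placed_r = np.empty(n)
    k = 0
    chunk = 64
    for idx in order:
        r = radii[idx]
        lo, hi = r, fov_um - r
        if hi <= lo:
            raise PlacementError(f"vesicle of radius {r:.2f} um does not fit in the FOV")
        ok = False
        attempts = 0
        while attempts < max_attempts:
            cand = rng.uniform(lo, hi, size=(chunk, 2))
            attempts += chunk
            if k == 0:
                pick = 0
            else:
                d = np.linalg.norm(cand[:, None, :] - placed_xy[None, :k, :], axis=-1)
                valid = (d >= placed_r[:k] + r + min_gap_um).all(axis=1)
                if not valid.any():
                    continue
                pick = int(np.argmax(valid))
            centers[idx] = cand[pick]
            placed_xy[k] = cand[pick]
            placed_r[k] = r
            k += 1
            ok = True
            break
        if not ok:
            return None
    return centers


def sample_population(
    config: PopulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[list[LiposomeState]]:
    """Sample per-FOV liposome populations from a mixture configuration.

    Each liposome's genotype is drawn with probability equal to its
    population's volume fraction, the expressing flag independently with
    ``p_expression``, and its localization state from the genotype's
    phenotype (non-expressing liposomes behave as phenotype ``none``).
    Centers are uniform within the FOV subject to a minimum spacing of
    r_i + r_j + 1 um so that rendered vesicles never overlap.
    """
    fractions = config.volume_fractions()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = _as_rng(rng)
    lo_n, hi_n = config.liposomes_per_fov
    if not (0 < lo_n <= hi_n):
        raise ConfigurationError("liposomes_per_fov bounds must satisfy 0 < lo <= hi")
    med, sig = config.diameter_lognormal
    d_lo, d_hi = config.diameter_range_um
    specs = [g for g, _ in config.components]

    fovs: list[list[LiposomeState]] = []
    next_id = 0
    for fov_idx in range(config.n_fov):
        n = int(rng.integers(lo_n, hi_n + 1))
        centers = None
        for _restart in range(5):
            # a fresh diameter draw on each restart: an unluckily large draw
            # can be geometrically unplaceable no matter the positions
            diam = _sample_diameters(n, med, sig, d_lo, d_hi, rng)
            centers = _place_centers(diam / 2.0, config.fov_um, config.min_gap_um, rng)
            if centers is not None:
                break
        if centers is None:
            raise PlacementError(f"FOV {fov_idx}: could not place {n} vesicles with the required spacing")
        gidx = rng.choice(len(specs), size=n, p=fractions)
        expressing = rng.random(n) < config.p_expression
        lipos = []
        for i in range(n):
            spec = specs[int(gidx[i])]
            phen = spec.phenotype if expressing[i] else "none"
            weights = (
                config.mode_weights
                if (config.mode_weights is not None and phen == "oscillatory")
                else default_mode_weights(phen)
            )
            osc = assign_oscillation(None, weights, rng)
            lipos.append(
                LiposomeState(
                    id=next_id,
                    genotype=spec,
                    center_um=(float(centers[i, 0]), float(centers[i, 1])),
                    diameter_um=float(diam[i]),
                    expressing=bool(expressing[i]),
                    osc=osc,
                    fov=fov_idx,
                )
            )
            next_id += 1
        fovs.append(lipos)
    return fovs


def population_to_csv(fovs: Sequence[Sequence[LiposomeState]], path) -> None:
    """Write ground truth as CSV, one row per liposome."""
    cols = ["id", "fov", "genotype", "x_um", "y_um", "diameter_um", "expressing", "mode", "period_s", "activated"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for fov in fovs:
            for lp in fov:
                w.writerow(
                    [
                        lp.id,
                        lp.fov,
                        lp.genotype.name,
                        f"{lp.center_um[0]:.3f}",
                        f"{lp.center_um[1]:.3f}",
                        f"{lp.diameter_um:.3f}",
                        int(lp.expressing),
                        lp.osc.mode,
                        "" if lp.osc.period_s is None else f"{lp.osc.period_s:.2f}",
                        int(lp.activated),
                    ]
                )


# --------------------------------------------------------------------------
# Synthetic amplicon reads


_BASES = np.array(list("ACGT"))


def _deterministic_sequence(length: int, tag: str) -> str:
    """Reproducible pseudo-random nucleotide sequence keyed by a string tag."""
    rng = np.random.default_rng(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class MtsLibrary:
    """A shared amplicon backbone with a 6-nt variant window.

    The backbone models a single amplified locus (default 1398 bp, the
    length of the minD amplicon); all variants are identical outside a
    two-codon window in the membrane targeting sequence.  ``left_flank``
    and ``right_flank`` are the 12-nt anchors immediately bordering the
    window, used downstream for anchored variant extraction.
    """

    backbone: str
    window_start: int
    variants: Mapping[str, str]

    @property
    def left_flank(self) -> str:
        return self.backbone[self.window_start - 12 : self.window_start]

    @property
    def right_flank(self) -> str:
        return self.backbone[self.window_start + 6 : self.window_start + 18]

    def sequence_of(self, name: str) -> str:
        if name not in self.variants:
            raise InputError(f"unknown variant {name!r}")
        w = self.variants[name]
        return self.backbone[: self.window_start] + w + self.backbone[self.window_start + 6 :]


#: Two-codon windows for the nine-variant library.  Var1 is the wild type
#: hydrophobic patch (Phe-Leu); Var7 is the F,L -> L,H substitution; the
#: remaining windows substitute charged/polar codons (non-binders).
DEFAULT_MTS_WINDOWS = {
    "Var1": "TTCCTG",  # F L  (wild type)
    "Var2": "GAACTG",  # E L
    "Var3": "AAACGT",  # K R
    "Var4": "GATGAA",  # D E
    "Var5": "AGCAAC",  # S N
    "Var6": "CAGAAA",  # Q K
    "Var7": "CTGCAT",  # L H  (functional)
    "Var8": "CGTGAT",  # R D
    "Var9": "AACAGC",  # N S
}


def make_mts_library(
    amplicon_length: int = 1398,
    window_start: int = 450,
    windows: Mapping[str, str] | None = None,
) -> MtsLibrary:
    """Build the synthetic variant library on a deterministic backbone."""
    if windows is None:
        windows = DEFAULT_MTS_WINDOWS
    if window_start < 12 or window_start + 18 > amplicon_length:
        raise ConfigurationError("variant window must leave room for 12-nt flanks")
    backbone = _deterministic_sequence(amplicon_length, f"mts-backbone-{amplicon_length}")
    return MtsLibrary(backbone=backbone, window_start=window_start, variants=dict(windows))


def _mutate(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
    for i in hits:
        arr[i] = lut[int(arr[i])][rng.integers(0, 3)]
    return arr.tobytes().decode()


def generate_reads(
    variant_fractions: Mapping[str, float],
    n_reads: int,
    error_rate: float = 0.0,
    length_model: Mapping[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
    library: MtsLibrary | None = None,
    junk_fraction: float = 0.0,
) -> list[SeqRecord]:
    """Synthesize FASTQ records for a pool of amplicon variants.

    Each read carries the full-length amplicon with the variant's 6-nt
    window substituted, per-base substitution errors at ``error_rate`` and
    Gaussian length jitter (``length_model = {"sd_bp": ...}``, trimmed from
    the read ends).  A ``junk_fraction`` of reads are random sequences with
    lengths outside the 1100-1400 bp recovery window, emulating off-length
    PCR products.  Base qualities are constant Q20.
    """
    if n_reads < 0:
        raise InputError("n_reads must be >= 0")
    rng = _as_rng(rng)
    if library is None:
        library = make_mts_library()
    names = list(variant_fractions.keys())
    fr = np.asarray([variant_fractions[k] for k in names], dtype=float)
    if n_reads > 0 and abs(fr.sum() - 1.0) > 1e-9:
        raise InputError("variant fractions must sum to 1")
    for nm in names:
        if nm not in library.variants:
            raise InputError(f"unknown variant name {nm!r}")
    sd_bp = float((length_model or {}).get("sd_bp", 25.0))

    records: list[SeqRecord] = []
    if n_reads == 0:
        return records
    is_junk = rng.random(n_reads) < junk_fraction
    choices = rng.choice(len(names), size=n_reads, p=fr)
    for i in range(n_reads):
        if is_junk[i]:
            # off-length product: short fragment or concatemer-like overlength
            if rng.random() < 0.8:
                ln = int(rng.integers(300, 1050))
            else:
                ln = int(rng.integers(1450, 1650))
            seq = "".join(_BASES[rng.integers(0, 4, size=ln)])
            name = f"junk_{i}"
        else:
            variant = names[int(choices[i])]
            seq = library.sequence_of(variant)
            if sd_bp > 0:
                ln = int(round(rng.normal(len(seq), sd_bp)))
                ln = max(600, min(len(seq), ln))
                if ln < len(seq):
                    cut = len(seq) - ln
                    left = int(rng.integers(0, cut + 1))
                    seq = seq[left : left + ln]
            seq = _mutate(seq, error_rate, rng)
            if rng.random() < 0.5:  # either strand comes off the sequencer
                seq = str(Seq(seq).reverse_complement())
            name = f"read_{i}_{variant}"
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [20] * len(seq)
        records.append(rec)
    return records


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    """Write records as standard 4-line FASTQ; returns the record count."""
    with open(path, "w") as fh:
        return SeqIO.write(records, fh, "fastq")
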