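"""The seven RNA sequence-encoding schemes.

Composition encoders
    * k-mer composition (default k=2, 16 features)
    * reverse-complement k-mer composition (strand-agnostic, 10 features
      at k=2 after merging each k-mer with its reverse complement)
    * pseudo di-/tri-nucleotide composition, pure composition tier
      (16 and 64 features)

Physicochemical covariance encoders
    * TAC — trinucleotide auto-covariance (2 properties x 2 lags = 4)
    * TCC — trinucleotide cross-covariance (2x1 ordered property pairs
      x 2 lags = 4)
    * DCC — dinucleotide cross-covariance (6x5 ordered pairs x 2 lags = 60)

Covariance features are mean-centered lagged products of a standardized
physicochemical property profile along the sequence:

    AC(u, l)      = 1/(N-l) * sum_i (P_u(i) - mean(P_u)) (P_u(i+l) - mean(P_u))
    CC(u1, u2, l) = 1/(N-l) * sum_i (P_u1(i) - mean(P_u1)) (P_u2(i+l) - mean(P_u2))

where P_u(i) is the standardized value of property u for the k-word
starting at position i and N = L - k + 1 is the profile length.

With the default configuration the seven encoders emit
16 + 10 + 16 + 64 + 4 + 4 + 60 = 174 features in total.

Feature names are namespaced ("kmer:AA", "dcc:roll*twist@lag1", ...) so the
fused hybrid vector is self-describing. All encoders are pure functions:
the same sequence always yields a bit-identical vector.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path

import numpy as np

from .sequence_io import RnaSequence

ALPHABET = "ACGU"
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

__all__ = [
    "FeatureVector",
    "PropertyTable",
    "EncoderConfig",
    "ENCODER_NAMES",
    "kmer_words",
    "encode_kmer",
    "reverse_complement",
    "canonical_rc_kmers",
    "encode_rc_kmer",
    "encode_pse_dnc",
    "encode_pse_tnc",
    "property_profile",
    "encode_tac",
    "encode_tcc",
    "encode_dcc",
    "encode_sequence",
    "load_property_table",
    "default_dinucleotide_table",
    "default_trinucleotide_table",
]


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered real-valued features for one sequence."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PropertyTable:
    """Complete physicochemical property table at di- or tri-nucleotide
    granularity.

    ``values[word]`` is the vector of property values for that k-word,
    aligned with ``property_names``. :meth:`standardized` rescales every
    property to zero mean and unit variance across the 4^granularity
    k-words, which is the form the covariance encoders consume.
    """

    granularity: int
    property_names: tuple[str, ...]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.granularity not in (2, 3):
            raise ValueError("granularity must be 2 or 3")
        expected = set(kmer_words(self.granularity))
        if set(self.values) != expected:
            missing = sorted(expected - set(self.values))
            raise ValueError(f"property table incomplete; missing {missing[:5]}")
        for w, v in self.values.items():
            if len(v) != len(self.property_names):
                raise ValueError(f"word {w}: wrong number of property values")

    def standardized(self) -> "PropertyTable":
        words = kmer_words(self.granularity)
        mat = np.array([self.values[w] for w in words], dtype=float)
        mat = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        return PropertyTable(
            self.granularity,
            self.property_names,
            {w: mat[i] for i, w in enumerate(words)},
        )

    def column(self, prop: str) -> dict[str, float]:
        if prop not in self.property_names:
            raise KeyError(
                f"unknown property {prop!r}; table has {self.property_names}"
            )
        j = self.property_names.index(prop)
        return {w: float(v[j]) for w, v in self.values.items()}


def load_property_table(path: str | Path, granularity: int) -> PropertyTable:
    """Load a property table from CSV (header: k-word column then one
    column per property)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        props = tuple(header[1:])
        values = {
            row[0].upper().replace("T", "U"): np.array(row[1:], dtype=float)
            for row in reader
            if row
        }
    return PropertyTable(granularity, props, values)


def default_dinucleotide_table() -> PropertyTable:
    """Six RNA dinucleotide conformational parameters (shift, slide, rise,
    tilt, roll, twist), standardized over the 16 dinucleotides."""
    ref = resources.files("rna5hmc") / "data" / "dinucleotide_properties.csv"
    with resources.as_file(ref) as path:
        return load_property_table(path, granularity=2).standardized()


def default_trinucleotide_table() -> PropertyTable:
    """Two trinucleotide properties (roll, twist), each the mean over the
    trinucleotide's two overlapping dinucleotide steps, standardized over
    the 64 trinucleotides."""
    di = default_dinucleotide_table()
    roll, twist = di.column("roll"), di.column("twist")
    values = {
        w: np.array(
            [
                (roll[w[:2]] + roll[w[1:]]) / 2.0,
                (twist[w[:2]] + twist[w[1:]]) / 2.0,
            ]
        )
        for w in kmer_words(3)
    }
    return PropertyTable(3, ("roll", "twist"), values).standardized()


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration shared by all seven encoders.

    Defaults reproduce the standard dimensionalities: k-mer k=2 (16),
    RC-k-mer k=2 (10), PseDNC 16, PseTNC 64, TAC 2x2=4, TCC 2x1x2=4,
    DCC 6x5x2=60 — 174 hybrid features in total.
    """

    kmer_k: int = 2
    rc_kmer_k: int = 2
    cov_lag: int = 2
    di_properties: PropertyTable = field(default_factory=default_dinucleotide_table)
    tri_properties: PropertyTable = field(default_factory=default_trinucleotide_table)

    def __post_init__(self) -> None:
        if self.kmer_k < 1 or self.rc_kmer_k < 1 or self.cov_lag < 1:
            raise ValueError("kmer_k, rc_kmer_k and cov_lag must be >= 1")

    @property
    def min_length(self) -> int:
        """Shortest sequence every encoder can process."""
        return max(self.kmer_k, self.rc_kmer_k, 3, 3 + self.cov_lag)

    def dimensions(self) -> dict[str, int]:
        n_di = len(self.di_properties.property_names)
        n_tri = len(self.tri_properties.property_names)
        return {
            "kmer": 4**self.kmer_k,
            "rc_kmer": len(canonical_rc_kmers(self.rc_kmer_k)),
            "pse_dnc": 16,
            "pse_tnc": 64,
            "tac": n_tri * self.cov_lag,
            "tcc": n_tri * (n_tri - 1) * self.cov_lag,
            "dcc": n_di * (n_di - 1) * self.cov_lag,
        }


ENCODER_NAMES = ("kmer", "rc_kmer", "pse_dnc", "pse_tnc", "tac", "tcc", "dcc")


def kmer_words(k: int) -> list[str]:
    """All 4^k words over {A,C,G,U} in lexicographic order."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def _check_length(seq: RnaSequence, min_len: int, what: str) -> None:
    if len(seq) < min_len:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq)} but {what} "
            f"requires at least {min_len}"
        )


def _sliding_counts(residues: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(residues) - k + 1):
        w = residues[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def encode_kmer(seq: RnaSequence, k: int = 2, prefix: str = "kmer") -> FeatureVector:
    """Sliding-window k-mer frequencies: count(w) / (L - k + 1), over all
    4^k words in lexicographic order. Non-negative, sums to 1."""
    _check_length(seq, k, f"{k}-mer composition")
    n_windows = len(seq) - k + 1
    counts = _sliding_counts(seq.residues, k)
    words = kmer_words(k)
    values = np.array([counts.get(w, 0) / n_windows for w in words])
    return FeatureVector(tuple(f"{prefix}:{w}" for w in words), values)


def reverse_complement(seq: RnaSequence) -> RnaSequence:
    """Reverse the sequence and complement each base (A<->U, C<->G)."""
    return RnaSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1])


def _rc_word(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def canonical_rc_kmers(k: int) -> list[str]:
    """Sorted canonical representatives after merging each k-word with its
    reverse complement (canonical form = lexicographic min of the pair).

    For k=2 this yields 10 classes; for k=1, 2 (A~U, C~G); for k=3, 32.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted({min(w, _rc_word(w)) for w in kmer_words(k)})


def encode_rc_kmer(seq: RnaSequence, k: int = 2) -> FeatureVector:
    """Strand-agnostic k-mer composition: frequencies pooled over each
    reverse-complement equivalence class. Invariant under reverse
    complementation of the input; sums to 1."""
    _check_length(seq, k, f"RC {k}-mer composition")
    n_windows = len(seq) - k + 1
    counts = _sliding_counts(seq.residues, k)
    classes = canonical_rc_kmers(k)
    pooled = {c: 0 for c in classes}
    for w, n in counts.items():
        pooled[min(w, _rc_word(w))] += n
    values = np.array([pooled[c] / n_windows for c in classes])
    return FeatureVector(tuple(f"rckmer:{c}" for c in classes), values)


def encode_pse_dnc(seq: RnaSequence) -> FeatureVector:
    """Pseudo dinucleotide composition, pure composition tier: identical in
    value to 2-mer composition, 16 features."""
    return encode_kmer(seq, 2, prefix="psednc")


def encode_pse_tnc(seq: RnaSequence) -> FeatureVector:
    """Pseudo trinucleotide composition, pure composition tier: identical
    in value to 3-mer composition, 64 features."""
    return encode_kmer(seq, 3, prefix="psetnc")


def property_profile(
    seq: RnaSequence, table: PropertyTable, prop: str
) -> np.ndarray:
    """Positional profile of one property: entry i is the property value of
    the k-word starting at position i. Length L - granularity + 1."""
    g = table.granularity
    _check_length(seq, g, "property profile")
    col = table.column(prop)
    return np.array(
        [col[seq.residues[i : i + g]] for i in range(len(seq) - g + 1)]
    )


def _auto_covariance(profile: np.ndarray, lag: int) -> float:
    centered = profile - profile.mean()
    n = len(profile)
    return float(centered[: n - lag] @ centered[lag:]) / (n - lag)


def _cross_covariance(p1: np.ndarray, p2: np.ndarray, lag: int) -> float:
    c1 = p1 - p1.mean()
    c2 = p2 - p2.mean()
    n = len(p1)
    return float(c1[: n - lag] @ c2[lag:]) / (n - lag)


def encode_tac(seq: RnaSequence, cfg: EncoderConfig | None = None) -> FeatureVector:
    """Trinucleotide auto-covariance over each property profile at lags
    1..cov_lag. Vanishes on homopolymers (constant profile)."""
    cfg = cfg or EncoderConfig()
    _check_length(seq, 3 + cfg.cov_lag, "trinucleotide auto-covariance")
    names, values = [], []
    for prop in cfg.tri_properties.property_names:
        profile = property_profile(seq, cfg.tri_properties, prop)
        for lag in range(1, cfg.cov_lag + 1):
            names.append(f"tac:{prop}@lag{lag}")
            values.append(_auto_covariance(profile, lag))
    return FeatureVector(tuple(names), np.array(values))


def encode_tcc(seq: RnaSequence, cfg: EncoderConfig | None = None) -> FeatureVector:
    """Trinucleotide cross-covariance between every ordered pair of
    distinct properties at lags 1..cov_lag."""
    cfg = cfg or EncoderConfig()
    props = cfg.tri_properties.property_names
    if len(props) < 2:
        raise ValueError("cross-covariance needs at least 2 properties")
    _check_length(seq, 3 + cfg.cov_lag, "trinucleotide cross-covariance")
    profiles = {
        p: property_profile(seq, cfg.tri_properties, p) for p in props
    }
    names, values = [], []
    for u1 in props:
        for u2 in props:
            if u1 == u2:
                continue
            for lag in range(1, cfg.cov_lag + 1):
                names.append(f"tcc:{u1}*{u2}@lag{lag}")
                values.append(_cross_covariance(profiles[u1], profiles[u2], lag))
    return FeatureVector(tuple(names), np.array(values))


def encode_dcc(seq: RnaSequence, cfg: EncoderConfig | None = None) -> FeatureVector:
    """Dinucleotide cross-covariance between every ordered pair of distinct
    dinucleotide properties at lags 1..cov_lag (6 properties -> 60 features
    by default)."""
    cfg = cfg or EncoderConfig()
    props = cfg.di_properties.property_names
    if len(props) < 2:
        raise ValueError("cross-covariance needs at least 2 properties")
    _check_length(seq, 2 + cfg.cov_lag, "dinucleotide cross-covariance")
    profiles = {
        p: property_profile(seq, cfg.di_properties, p) for p in props
    }
    names, values = [], []
    for u1 in props:
        for u2 in props:
            if u1 == u2:
                continue
            for lag in range(1, cfg.cov_lag + 1):
                names.append(f"dcc:{u1}*{u2}@lag{lag}")
                values.append(_cross_covariance(profiles[u1], profiles[u2], lag))
    return FeatureVector(tuple(names), np.array(values))


def encode_sequence(
    seq: RnaSequence,
    cfg: EncoderConfig | None = None,
    only: str | None = None,
) -> FeatureVector:
    """Run one encoder (``only``) or the full seven-encoder concatenation
    in the fixed hybrid order: kmer, rc_kmer, pse_dnc, pse_tnc, tac, tcc,
    dcc."""
    cfg = cfg or EncoderConfig()
    dispatch = {
        "kmer": lambda s: encode_kmer(s, cfg.kmer_k),
        "rc_kmer": lambda s: encode_rc_kmer(s, cfg.rc_kmer_k),
        "pse_dnc": encode_pse_dnc,
        "pse_tnc": encode_pse_tnc,
        "tac": lambda s: encode_tac(s, cfg),
        "tcc": lambda s: encode_tcc(s, cfg),
        "dcc": lambda s: encode_dcc(s, cfg),
    }
    if only is not None:
        if only not in dispatch:
            raise ValueError(f"unknown encoder {only!r}; choose from {ENCODER_NAMES}")
        return dispatch[only](seq)
    parts = [dispatch[name](seq) for name in ENCODER_NAMES]
    return FeatureVector(
        tuple(n for p in parts for n in p.names),
        np.concatenate([p.values for p in parts]),
    )
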