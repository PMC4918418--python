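"""Readers and writers for the plain-text formats used across the package.

Covers PAML-style ``.dat`` substitution-model files (lower-triangle
exchangeabilities in the PAML amino acid order plus a frequency vector),
profile/matrix TSVs with one-letter amino acid headers, mixture-class
tables, contact maps, and trajectory JSON-lines.  All in-memory arrays use
the package's alphabetical amino acid order; files in PAML format keep the
PAML convention for interchange with published matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .genetic_code import AA_ALPHABET, PAML_AA_ORDER, PAML_TO_ALPHA

#: Names of the bundled published substitution models.
BUNDLED_MODELS = ("wag", "jtt", "lg", "dayhoff", "blosum62")

_ALPHA_TO_PAML = np.argsort(PAML_TO_ALPHA)


@dataclass(frozen=True)
class StandardModel:
    """A published 20-state model: symmetric exchangeabilities + frequencies.

    Arrays are in alphabetical amino acid order.
    """

    name: str
    exchangeability: np.ndarray
    frequencies: np.ndarray


def read_paml_dat(path) -> StandardModel:
    """Read a PAML-style .dat file (lower triangle + frequencies)."""
    vals = [float(tok) for tok in Path(path).read_text().split()]
    if len(vals) < 210:
        raise ValueError(f"{path}: expected 190 exchangeabilities + 20 frequencies")
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = vals[k]
            k += 1
    freqs = np.asarray(vals[k : k + 20])
    # reorder from PAML convention to alphabetical
    S = S[np.ix_(PAML_TO_ALPHA, PAML_TO_ALPHA)]
    freqs = freqs[PAML_TO_ALPHA]
    return StandardModel(name=Path(path).stem, exchangeability=S, frequencies=freqs / freqs.sum())


def write_paml_dat(path, exchangeability: np.ndarray, frequencies: np.ndarray) -> None:
    """Write a symmetric 20x20 matrix + frequencies in PAML .dat convention."""
    S = np.asarray(exchangeability, dtype=float)
    if S.shape != (20, 20) or np.max(np.abs(S - S.T)) > 1e-12:
        raise ValueError("exchangeability matrix must be symmetric 20x20")
    S = S[np.ix_(_ALPHA_TO_PAML, _ALPHA_TO_PAML)]
    f = np.asarray(frequencies, dtype=float)[_ALPHA_TO_PAML]
    with open(path, "w") as fh:
        for i in range(1, 20):
            fh.write(" ".join(f"{S[i, j]:.8g}" for j in range(i)) + "\n")
        fh.write("\n")
        fh.write(" ".join(f"{x:.8g}" for x in f) + "\n")


def load_standard_model(name: str) -> StandardModel:
    """Load one of the bundled published models (wag, jtt, lg, dayhoff, blosum62)."""
    name = name.lower()
    if name not in BUNDLED_MODELS:
        raise ValueError(f"unknown bundled model {name!r}; choose from {BUNDLED_MODELS}")
    ref = resources.files("mutselhet.data") / f"{name}.dat"
    with resources.as_file(ref) as path:
        model = read_paml_dat(path)
    return StandardModel(name=name, exchangeability=model.exchangeability,
                         frequencies=model.frequencies)


# ---------------------------------------------------------------------------
# TSV formats


def write_matrix_tsv(path, M: np.ndarray, comments=()) -> None:
    """Write a 20x20 matrix as TSV with a one-letter amino acid header."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t" + "\t".join(AA_ALPHABET) + "\n")
        for a, row in zip(AA_ALPHABET, np.asarray(M, dtype=float)):
            fh.write(a + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_matrix_tsv(path) -> np.ndarray:
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "":  # header
                header = parts[1:]
                continue
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if set(rows) != set(AA_ALPHABET):
        raise ValueError("matrix TSV must have one row per amino acid")
    perm = [header.index(a) for a in AA_ALPHABET]
    return np.array([[rows[a][j] for j in perm] for a in AA_ALPHABET])


def write_profiles_tsv(path, profiles: np.ndarray, site_indices=None, comments=()) -> None:
    """Write site profiles as TSV: site index + 20 frequency columns."""
    P = np.asarray(profiles, dtype=float)
    idx = np.arange(P.shape[0]) if site_indices is None else np.asarray(site_indices)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("site\t" + "\t".join(AA_ALPHABET) + "\n")
        for i, row in zip(idx, P):
            fh.write(f"{i}\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_profiles_tsv(path):
    """Read site profiles; returns (site_indices, (n, 20) array)."""
    idx, rows = [], []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                continue
            idx.append(int(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    P = np.asarray(rows, dtype=float)
    perm = [header[1:].index(a) for a in AA_ALPHABET]
    return np.asarray(idx), P[:, perm]


def read_mixture_tsv(path):
    """Read mixture classes: 20 frequency columns plus a 'weight' column.

    Returns (class_profiles (k, 20), weights (k,)).
    """
    rows, weights = [], []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if header is None:
                header = parts
                if "weight" not in header:
                    raise ValueError("mixture TSV needs a 'weight' column")
                continue
            rec = dict(zip(header, parts))
            rows.append([float(rec[a]) for a in AA_ALPHABET])
            weights.append(float(rec["weight"]))
    P = np.asarray(rows, dtype=float)
    P = P / P.sum(axis=1, keepdims=True)
    w = np.asarray(weights, dtype=float)
    return P, w / w.sum()


def write_omega_points_tsv(path, points, comments=()) -> None:
    """Write OmegaPoint records as TSV (label, omega_eff, rate_ratio [+ CI])."""
    cols = ["label", "omega_eff", "rate_ratio",
            "omega_eff_lo", "omega_eff_hi", "rate_ratio_lo", "rate_ratio_hi"]
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for p in points:
            vals = [p.label] + [
                "" if getattr(p, c) is None else f"{getattr(p, c):.6g}" for c in cols[1:]
            ]
            fh.write("\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# Contact maps and trajectories


def write_contact_map(path, structure) -> None:
    """Write a contact map as two-column TSV with an 'n_residues=N' header."""
    with open(path, "w") as fh:
        fh.write(f"n_residues={structure.n_residues}\n")
        for i, j in structure.contacts:
            fh.write(f"{i}\t{j}\n")


def read_contact_map(path):
    """Read a contact map TSV; returns a ContactStructure."""
    from .stability import ContactStructure

    pairs = []
    n_residues = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("n_residues="):
                n_residues = int(line.split("=", 1)[1])
                continue
            i, j = line.split("\t")
            pairs.append((int(i), int(j)))
    if n_residues is None:
        raise ValueError(f"{path}: missing 'n_residues=N' header line")
    return ContactStructure(n_residues=n_residues, contacts=np.asarray(pairs, dtype=int).reshape(-1, 2))


def write_trajectory_jsonl(path, trajectory) -> None:
    """Write a simulation trajectory as JSON-lines (config, events, samples)."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"kind": "config", **trajectory.config,
                             "start_codons": list(trajectory.start_codons)}) + "\n")
        for t, site, frm, to in trajectory.iter_events():
            fh.write(json.dumps({"kind": "event", "time": t, "site": int(site),
                                 "from_codon": frm, "to_codon": to}) + "\n")
        for k, t in enumerate(trajectory.sample_times):
            fh.write(json.dumps({
                "kind": "sample", "time": float(t),
                "dG": float(trajectory.sample_dG[k]),
                "profiles": np.round(trajectory.sample_profiles[k], 8).tolist(),
            }) + "\n")
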