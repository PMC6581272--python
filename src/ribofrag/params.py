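"""Model parameters for the fragmented-replicase protocell model.

The chemistry is the three-reaction network

    X + Y  --k_f-->  C            (self-assembly of the catalyst)
    C      --k_b-->  X + Y        (disassembly)
    X + C  --k_x-->  2X + C       (replication of fragment X)
    Y + C  --k_y-->  2Y + C       (replication of fragment Y)

run either deterministically in a well-mixed batch, or stochastically
inside ``N_cell`` protocells that divide when their fragment count
reaches ``V_div`` and exchange molecules at per-molecule rate ``D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class ModelParams:
    """All rate constants and population-level parameters, validated.

    Parameters
    ----------
    k_f : float
        Assembly rate of X + Y -> C (concentration^-1 time^-1).
    k_b : float
        Disassembly rate of C -> X + Y (time^-1).
    k_x, k_y : float
        Replication rates of the two fragments (concentration^-1 time^-1).
    D : float
        Horizontal-transfer constant: per-molecule rate of leaving a cell
        (time^-1).
    V_div : int
        Division threshold: total fragment count (free fragments plus two
        per catalyst) that triggers cell division.
    N_cell : int
        Number of protocells, held constant across divisions.
    p_loss : float
        Probability that a transferred molecule is destroyed in transit
        instead of delivered (default 0).
    n_frag : int
        Number of fragment species in the N-fragment batch generalization
        (default 2; the protocell simulator supports n_frag = 2 only).
    """

    k_f: float = 1.0
    k_b: float = 1.0
    k_x: float = 1.0
    k_y: float = 1.0
    D: float = 0.0
    V_div: int = 1000
    N_cell: int = 100
    p_loss: float = 0.0
    n_frag: int = 2

    def __post_init__(self) -> None:
        for name in ("k_f", "k_b", "k_x", "k_y", "D"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValueError(f"rate {name} must be >= 0, got {v!r}")
        if self.V_div < 4:
            raise ValueError(f"V_div must be >= 4, got {self.V_div}")
        if self.N_cell < 1:
            raise ValueError(f"N_cell must be >= 1, got {self.N_cell}")
        if not 0.0 <= self.p_loss <= 1.0:
            raise ValueError(f"p_loss must be in [0, 1], got {self.p_loss}")
        if self.n_frag < 2:
            raise ValueError(f"n_frag must be >= 2, got {self.n_frag}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)
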