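"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`EntrankError`
so the CLI can map data/validation problems to a distinct exit status.
"""


class EntrankError(Exception):
    """Base class for all entrank errors."""


class FormatError(EntrankError):
    """A file does not conform to the expected delimited-text layout."""


class ValidationError(EntrankError):
    """An in-memory object violates a domain invariant."""


class DegenerateInputError(EntrankError):
    """The requested quantity is undefined for this input (e.g. S = 1)."""


class CyclicRelationError(EntrankError):
    """The pairwise majority relation contains a Condorcet cycle."""

    def __init__(self, cycles):
        self.cycles = list(cycles)
        listing = "; ".join(" > ".join([*c, c[0]]) for c in self.cycles)
        super().__init__(
            f"majority relation is intransitive (Condorcet cycle): {listing}"
        )


class AlgorithmFailure(EntrankError):
    """A clustering run failed (non-convergence, empty clusters, ...)."""
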