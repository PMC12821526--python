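"""Exception hierarchy for nbquant.

Every error raised on a contract violation derives from :class:`NbquantError`
so callers can catch pipeline failures with a single except clause while
letting programming errors propagate.
"""


class NbquantError(Exception):
    """Base class for all nbquant errors."""


class StackIOError(NbquantError):
    """An image file could not be read or written."""


class ConfigurationError(NbquantError):
    """Invalid or incomplete run configuration (missing voxel size,
    unknown ids, bad channel mapping, out-of-range parameters)."""


class ConsistencyError(NbquantError):
    """Internal data structures disagree (shape mismatches, empty voxel
    sets, mixed nucleus ids)."""


class InputError(NbquantError):
    """A statistical routine received data it cannot analyse
    (empty sample, too few groups, sample size out of range)."""


class GenerationError(NbquantError):
    """The synthetic-data generator could not realise the requested
    configuration (e.g. infeasible spot packing)."""


class PipelineError(NbquantError):
    """A pipeline stage failed; carries the stage name and source id."""

    def __init__(self, stage: str, source_id: str, message: str):
        self.stage = stage
        self.source_id = source_id
        super().__init__(f"[{stage}] {source_id}: {message}")
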