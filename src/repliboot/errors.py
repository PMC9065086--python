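"""Exception hierarchy shared across repliboot modules."""


class ReplibootError(Exception):
    """Base class for all repliboot-specific errors."""


class DomainError(ReplibootError, ValueError):
    """A parameter is outside its valid domain (e.g. pi <= 0, weights not summing to 1)."""


class FormatError(ReplibootError, ValueError):
    """An input file violates its format contract (FASTQ/TSV/GMT)."""


class FastqFormatError(FormatError):
    """Malformed FASTQ record; the message names the offending record index."""


class PairingError(ReplibootError, ValueError):
    """Paired FASTQ mates disagree (unequal read counts or mismatched ids)."""


class DesignError(ReplibootError, ValueError):
    """Invalid experimental design (missing levels, empty level, wrong level count)."""


class DegreesOfFreedomError(DesignError):
    """Too few samples for the requested design factor."""


class InsufficientDataError(ReplibootError, ValueError):
    """Not enough complete observations to compute the requested statistic."""
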