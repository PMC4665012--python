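"""Exception types shared across the package."""


class ViropanelError(Exception):
    """Base class for data-level errors (exit code 1 in the CLI)."""


class FastaParseError(ViropanelError):
    """Malformed FASTA input; the message names the offending line."""


class ContractError(ViropanelError):
    """A caller violated a documented precondition."""
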