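"""Exception hierarchy."""


class DtlCoevError(Exception):
    """Base class for all package errors."""


class TreeError(DtlCoevError):
    """Invalid species or gene tree (topology, dating, labels)."""


class MappingError(DtlCoevError):
    """Gene leaves cannot be resolved to species."""


class EventSetError(DtlCoevError):
    """Malformed weighted event set (bad weight, type or branch)."""


class ReconciliationError(DtlCoevError):
    """Reconciliation cannot be computed or enumeration refused."""
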