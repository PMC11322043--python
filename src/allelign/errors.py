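"""Exception and warning types shared across the package."""


class AllelignError(Exception):
    """Base class for all package-specific errors."""


class UnrecognizedChromosome(AllelignError):
    """A chromosome label outside the 1-22/X/Y/MT alias set."""


class MalformedIndex(AllelignError):
    """A canonical index string without exactly four colon-separated fields."""


class RegistryExists(AllelignError):
    """Attempt to create a registry over an existing one without force."""


class RegistryNotFound(AllelignError):
    """Attempt to load a registry that does not exist on disk."""


class PathNotWritable(AllelignError):
    """Registry root directory is not writable."""


class DuplicatePositionInBatch(AllelignError):
    """Two records in one register_novel batch share (chrom, pos)."""


class MissingColumn(AllelignError):
    """A mandatory column role is absent from an input file."""


class NonFiniteStatistic(AllelignError):
    """An effect size or frequency is NaN/inf (or an odds ratio is zero)."""


class DuplicateChromosomeReport(AllelignError):
    """The same chromosome supplied twice to merge."""


class MixedDatasetLabels(AllelignError):
    """Per-chromosome reports from different datasets supplied to one merge."""


class RegistryMismatch(AllelignError):
    """Composites realigned against different registries passed to intersect."""


class MissingVariant(AllelignError):
    """A scoring weight refers to a variant absent from the genotype matrix."""


class InvalidRate(AllelignError):
    """A rate parameter outside [0, 1]."""


class InfeasibleCounts(AllelignError):
    """Simulation counts that cannot be satisfied (e.g. n_shared > n_variants)."""


class EmptyInputWarning(UserWarning):
    """An input yielded zero valid biallelic SNPs; empty reports were emitted."""


class SingleDatasetWarning(UserWarning):
    """Intersection requested over a single dataset (result is that dataset)."""
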