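# Default deleteriousness-metric transformation table.
#
# Each stanza defines how one variant-level pathogenicity metric is mapped
# onto the common [0, 1] deleteriousness scale D (0 = benign, 1 = maximally
# pathogenic):
#
#   D = clamp_then_rescale(raw)            if complement is false
#   D = 1 - clamp_then_rescale(raw)        if complement is true
#
# where clamp_then_rescale(raw) = (clamp(raw, lower, upper) - lower) / (upper - lower).
#
# Bounded metrics report in [0, 1] natively.  The five unbounded metrics
# (CADD, FATHMM, GERP++_RS, MetaSVM, phyloP) carry imposed ranges equal to
# the minimum/maximum values observed across the dbNSFP v3.3a SNV database;
# PROVEAN uses its documented score range.  MutationTaster's conditional
# rule keeps the scaled score for disease-causing predictions (classes A/D)
# and takes the complement for polymorphism predictions (classes N/P).
#
# Users may copy this file, edit bounds, and point the loader (or the
# --metric-config CLI option) at their copy.
CADD:           {category: composite,     lower: -7.53,  upper: 35.79, complement: false}
DANN:           {category: composite,     lower: 0.0,    upper: 1.0,   complement: false}
FATHMM:         {category: functionality, lower: -16.13, upper: 10.64, complement: true}
fathmm-MKL:     {category: composite,     lower: 0.0,    upper: 1.0,   complement: false}
GERP++_RS:      {category: conservation,  lower: -12.3,  upper: 6.17,  complement: false}
M-CAP:          {category: composite,     lower: 0.0,    upper: 1.0,   complement: false}
MetaLR:         {category: composite,     lower: 0.0,    upper: 1.0,   complement: false}
MetaSVM:        {category: composite,     lower: -2.0,   upper: 3.0,   complement: false}
MutationTaster: {category: functionality, lower: 0.0,    upper: 1.0,   complement: false, conditional: mutationtaster}
phastCons:      {category: conservation,  lower: 0.0,    upper: 1.0,   complement: false}
phyloP:         {category: conservation,  lower: -13.28, upper: 1.2,   complement: false}
Polyphen2_HDIV: {category: functionality, lower: 0.0,    upper: 1.0,   complement: false}
Polyphen2_HVAR: {category: functionality, lower: 0.0,    upper: 1.0,   complement: false}
PROVEAN:        {category: functionality, lower: -14.0,  upper: 14.0,  complement: true}
SIFT:           {category: functionality, lower: 0.0,    upper: 1.0,   complement: true}
VEST3:          {category: functionality, lower: 0.0,    upper: 1.0,   complement: false}
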