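term	category
auxin	hormone
abscisic	hormone
cytokinin	hormone
ethylene	hormone
gibberellin	hormone
brassinosteroid	hormone
hormone	hormone
cellulose	cell wall
expansin	cell wall
cell wall	cell wall
lignin	cell wall
xyloglucan	cell wall
phenylalanine ammonia	cell wall
pectin	cell wall
sucrose	sugar
glucose	sugar
fructose	sugar
amylase	sugar
starch	sugar
sugar	sugar
photosystem	photosynthesis
chlorophyll	photosynthesis
cryptochrome	photosynthesis
phytochrome	photosynthesis
far-red	photosynthesis
actin	cytoskeleton
tubulin	cytoskeleton
kinesin	cytoskeleton
myosin	cytoskeleton
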