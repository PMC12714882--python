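aardvark
alligator
alpaca
anchovy
ant
anteater
antelope
armadillo
baboon
badger
bass
bat
bear
beaver
bee
beetle
bison
bluejay
boar
bobcat
buffalo
butterfly
camel
canary
cardinal
cat
catfish
cheetah
chicken
chimpanzee
chinchilla
chipmunk
clam
cod
cougar
cow
coyote
crab
crane
crocodile
crow
deer
dog
dolphin
donkey
duck
eagle
eel
elephant
elk
emu
falcon
ferret
finch
fish
flamingo
fox
frog
gazelle
gecko
gerbil
giraffe
goat
goldfish
goose
gorilla
guinea_pig
hamster
hawk
hedgehog
heron
herring
hippopotamus
horse
hyena
iguana
impala
jackal
jaguar
jellyfish
kangaroo
koala
lemur
leopard
lion
lizard
llama
lobster
lynx
manatee
meerkat
mink
mole
mongoose
monkey
moose
moth
mouse
mule
mussel
narwhal
newt
octopus
okapi
opossum
orangutan
orca
ostrich
otter
owl
ox
oyster
panda
panther
parakeet
parrot
peacock
pelican
penguin
perch
pig
pigeon
platypus
porcupine
rabbit
raccoon
rat
raven
rhinoceros
robin
salamander
salmon
sardine
scorpion
seagull
seahorse
seal
shark
sheep
shrimp
skunk
sloth
slug
snail
snake
sparrow
spider
squid
squirrel
starfish
stingray
stork
swan
tapir
tiger
toad
tortoise
trout
tuna
turkey
turtle
walrus
warthog
wasp
weasel
whale
wildebeest
wolf
wolverine
worm
yak
zebra
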