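surface,root
aardvarks,aardvark
aligator,alligator
alligators,alligator
alpacas,alpaca
anchovies,anchovy
anteaters,anteater
antelopes,antelope
ants,ant
armadillos,armadillo
baboons,baboon
badgers,badger
basses,bass
bats,bat
bears,bear
beavers,beaver
bees,bee
beetles,beetle
bluejays,bluejay
boars,boar
bobcats,bobcat
buffalos,buffalo
butterflies,butterfly
camels,camel
canaries,canary
cardinals,cardinal
catfishes,catfish
cats,cat
cheeta,cheetah
cheetahs,cheetah
chickens,chicken
chimpanze,chimpanzee
chimpanzees,chimpanzee
chinchillas,chinchilla
chipmunks,chipmunk
clams,clam
cods,cod
cougars,cougar
cows,cow
coyotes,coyote
crabs,crab
cranes,crane
crocodiles,crocodile
crocodille,crocodile
crows,crow
dogs,dog
dolphins,dolphin
donkeys,donkey
ducks,duck
eagles,eagle
eels,eel
elefant,elephant
elephants,elephant
elks,elk
emus,emu
falcons,falcon
ferrets,ferret
finches,finch
fishes,fish
flamingoe,flamingo
flamingos,flamingo
foxes,fox
frogs,frog
gazelles,gazelle
geckos,gecko
geese,goose
gerbils,gerbil
girafe,giraffe
giraffes,giraffe
goats,goat
goldfishes,goldfish
gorillas,gorilla
guinea_pigs,guinea_pig
hampster,hamster
hamsters,hamster
hawks,hawk
hedgehogs,hedgehog
herons,heron
herrings,herring
hiena,hyena
hippopotami,hippopotamus
hippos,hippopotamus
horses,horse
hyenas,hyena
iguanas,iguana
impalas,impala
jackals,jackal
jaguars,jaguar
jellyfishes,jellyfish
kangaroos,kangaroo
koalas,koala
lemurs,lemur
leopards,leopard
leppard,leopard
lions,lion
lizards,lizard
llamas,llama
lobsters,lobster
lynxes,lynx
manatees,manatee
meerkats,meerkat
mice,mouse
minks,mink
moles,mole
mongooses,mongoose
monkeys,monkey
moths,moth
mules,mule
mussels,mussel
narwhals,narwhal
newts,newt
octopi,octopus
octopuses,octopus
okapis,okapi
opossums,opossum
orangutans,orangutan
orcas,orca
ostrage,ostrich
ostriches,ostrich
otters,otter
owls,owl
oxen,ox
oysters,oyster
pandas,panda
panthers,panther
parakeets,parakeet
parrots,parrot
peacocks,peacock
pelicans,pelican
penguins,penguin
perches,perch
pigeons,pigeon
pigs,pig
platypuses,platypus
porcupin,porcupine
porcupines,porcupine
rabbits,rabbit
raccoons,raccoon
racoon,raccoon
rats,rat
ravens,raven
rhinoceroses,rhinoceros
rhinos,rhinoceros
robins,robin
salamanders,salamander
salmons,salmon
sardines,sardine
scorpions,scorpion
seagulls,seagull
seahorses,seahorse
seals,seal
sharks,shark
shrimps,shrimp
skunks,skunk
sloths,sloth
slugs,slug
snails,snail
snakes,snake
sparrows,sparrow
spiders,spider
squids,squid
squirel,squirrel
squirrels,squirrel
starfishes,starfish
stingrays,stingray
storks,stork
swans,swan
tapirs,tapir
tigers,tiger
toads,toad
tortise,tortoise
tortoises,tortoise
trouts,trout
tunas,tuna
turkeys,turkey
turtles,turtle
walruses,walrus
warthogs,warthog
wasps,wasp
weasels,weasel
whales,whale
wildebeests,wildebeest
wolverines,wolverine
wolves,wolf
worms,worm
yaks,yak
zebras,zebra
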