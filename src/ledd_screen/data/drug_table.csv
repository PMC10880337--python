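drug_code,name,drug_class,rule_type,parameter,generation
levodopa,Levodopa,pd_drug,factor,1.0,
amantadine,Amantadine,pd_drug,factor,1.0,
benserazide,Benserazide,pd_drug,none,0.0,
carbidopa,Carbidopa,pd_drug,none,0.0,
entacapone,Entacapone,pd_drug,adjunct_levodopa,0.33,
pramipexole,Pramipexole,pd_drug,factor,100.0,
rasagiline,Rasagiline,pd_drug,factor,100.0,
ropinirole,Ropinirole,pd_drug,factor,20.0,
selegiline,Selegiline,pd_drug,factor,10.0,
azelastine,Azelastine,antihistamine,none,0.0,2
bepotastine,Bepotastine,antihistamine,none,0.0,2
cetirizine,Cetirizine,antihistamine,none,0.0,2
chlorpheniramine,Chlorpheniramine,antihistamine,none,0.0,1
clemastine,Clemastine,antihistamine,none,0.0,1
desloratadine,Desloratadine,antihistamine,none,0.0,2
dimenhydrinate,Dimenhydrinate,antihistamine,none,0.0,1
ebastine,Ebastine,antihistamine,none,0.0,2
fexofenadine,Fexofenadine,antihistamine,none,0.0,2
hydroxyzine,Hydroxyzine,antihistamine,none,0.0,1
ketotifen,Ketotifen,antihistamine,none,0.0,2
levocetirizine,Levocetirizine,antihistamine,none,0.0,2
loratadine,Loratadine,antihistamine,none,0.0,2
mizolastine,Mizolastine,antihistamine,none,0.0,2
olopatadine,Olopatadine,antihistamine,none,0.0,2
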