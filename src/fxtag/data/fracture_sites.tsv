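ankle	(inversion)?ankle |tillaux|bimalleolar |distal.*(fibular|tibial) |dupuytren’s |(lateral|medial|posterior) malleolus |Pott’s |trimalleolar
clavicle	(shaft|acromial end) of clavicle |interligamentous |collar bone |clavic(le|al) |clav |
distal_forearm	barton’s |colles’ |(distal|metaphyseal).*(wrist|radius|radial|ulna|ulnar|forearm) |smith’s |styloid process |head of ulna(r)? |ulna(r)? head |wrist
face	(inferior)?maxilla(ry)? |nasal |(upper|lower)?jaw |orbit(al)? |malar bone |palate |mandible |zygoma(tic)? |mandibular(ramus)? |facial |naso-orbital
feet_and_toes	(meta)?tarsal |astragalus |instep |calcaneus |os calcis |navicular |cuboid |cuneiform |talonavicular ossicle |heel |talus |phalan(x|ges?) |toe
hand_and_fingers	hand |fingers? |(meta)?carpals? |mc |(hand |finger) phalanges |(proximal|distal|middle).*phalanx |capitate |hamate |lunate |scaphoid |navicular |trapezi(um|id) |pisiform |triquetrum |metacarpus |bennett’s |thumb |sesamoid |boxer’s |bar room
other_spine	vertebra(e|l) |cervical vertebrae |posterior elements of vertebrae |coccyx |spinous process |neural arch |transverse process |spine |pedicle |C(1|2|3|4|5|6)
patella	knee ?(cap|pan) |patella(r)?
pelvis	acetabulum |acetabular |pelvic rim |ilium |pubis |pubic |innominate |rami |ischium |ischial |sacrum |sacral |obturator ring |pelvi(c|s)
proximal_femur	(femoral |femur)(head|neck) |(trans)?cervical |(sub)?capital |intracapsular |trans(|-)?epiphyseal |base of neck |basilar femoral neck |cervicotrochanteric |(greater|lesser) trochanter |(inter|per|intra)trochanteric
proximal_humerus	(anatomical|surgical)? (head|neck|head(-|/)neck|neck(-|/)head) |(humerus|humeral) (|shoulder |proximal end) |extra ?capsular |(humerus|humeral).*(head|neck|head(-|/)neck|neck(-|/)head) |head of (humerus|humeral) |(greater|lesser)? tuberosity |proximal humerus |humerus proximal
ribs	rib(s)? |(rib|thoracic) cage
scapula	acromion|coracoid(process)? |scapula |glenoid(cavity|fossa)? |shoulder blade
shaft_and_distal_femur	diaphyseal fracture of femur |subtrochanteric |(lateral|medial) condylar |supracondylar |(shaft|lower end) of femur |mid femur
shaft_and_distal_humerus	elbow |condylar |shaft of (humerus|humeral) |(distal|end of|shaft).*(humerus|humeral) |supracondylar |epicondyle
shaft_and_proximal_radius_ulna	proximal.*(forearm|radius|radial|ulna(r)?) |coronoid process |metaphyseal of (the)?proximal.*(forearm|radius|radial|ulna(r)?) |(radius|ulna) diaphyseal |Monteggia(’s)? |Dupuytren(’s)? |(neck|head|head(-|/)neck|neck(-|/)head) of.*(radius|radial) |(radius|radial) (neck|head|head(-|/)neck|neck(-|/)head) |Galeazzi(’s)? |shaft (of)? (ulna(r)? |radius)|radial shalf |ulna(r)? shaft |metadiaphyseal |olecranon(process)?
skull	(base|vault) of the skull |vault |(ethmoid|sphenoid) (sinus|base) |sphenoid |occipital |vertex skull |calvaria(l)? |calvarium
sternum	breast()?bone |sternum |manubrium |xyphoid
tibia_and_fibula	(proximal)?fibula |intercondylar eminence shaft |(lateral|tibia |fibula) condyle |lateral tibial plateau |((medial)?tibia |tibial) shaft |tuberosity
vertebral_body	ballooning (of inter ?spaces?)? |biconcave |burst |axis |cod-fish |endplate |loss of height ||(t|l)-?spine |lumbar |thoracic |collapse |l(1|2|3|4|5) |t(1|2|3|4|5|6|7|8|9|10|11)
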