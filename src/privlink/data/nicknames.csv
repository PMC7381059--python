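nickname,canonical
ABBY,ABIGAIL
ABE,ABRAHAM
AL,ALBERT
ALEX,ALEXANDER
ALLIE,ALISON
ANDY,ANDREW
ANGIE,ANGELA
ANNIE,ANNE
ARCHIE,ARCHIBALD
BARB,BARBARA
BART,BARTHOLOMEW
BECKY,REBECCA
BELLA,ISABELLA
BEN,BENJAMIN
BERNIE,BERNARD
BERT,ALBERT
BESS,ELIZABETH
BETH,ELIZABETH
BETSY,ELIZABETH
BETTY,ELIZABETH
BILL,WILLIAM
BILLY,WILLIAM
BOB,ROBERT
BOBBY,ROBERT
BRAD,BRADLEY
CAM,CAMERON
CARRIE,CAROLINE
CASSIE,CASSANDRA
CATH,CATHERINE
CATHY,CATHERINE
CHARLIE,CHARLES
CHAS,CHARLES
CHRIS,CHRISTOPHER
CHRISSY,CHRISTINE
CHUCK,CHARLES
CINDY,CYNTHIA
CLIFF,CLIFFORD
CONNIE,CONSTANCE
DAN,DANIEL
DANNY,DANIEL
DAVE,DAVID
DEB,DEBORAH
DEBBIE,DEBORAH
DICK,RICHARD
DOM,DOMINIC
DON,DONALD
DONNIE,DONALD
DOTTIE,DOROTHY
DOUG,DOUGLAS
ED,EDWARD
EDDIE,EDWARD
ELIZA,ELIZABETH
ELLIE,ELEANOR
EM,EMILY
EMMY,EMILY
FRED,FREDERICK
FREDDIE,FREDERICK
GABBY,GABRIELLA
GABE,GABRIEL
GERRY,GERALD
GREG,GREGORY
GUS,ANGUS
HANK,HENRY
HARRY,HENRY
JACK,JOHN
JAKE,JACOB
JEN,JENNIFER
JENNY,JENNIFER
JERRY,GERALD
JESS,JESSICA
JESSIE,JESSICA
JIM,JAMES
JIMMY,JAMES
JOE,JOSEPH
JOEY,JOSEPH
JOHNNY,JOHN
JON,JONATHAN
JOSH,JOSHUA
JUDE,JUDITH
JUDY,JUDITH
KATE,KATHERINE
KATIE,KATHERINE
KATHY,KATHERINE
KEN,KENNETH
KENNY,KENNETH
KIM,KIMBERLY
LARRY,LAWRENCE
LEN,LEONARD
LEO,LEONARD
LIZ,ELIZABETH
LIZZIE,ELIZABETH
LOU,LOUIS
LUKE,LUCAS
MAGGIE,MARGARET
MANDY,AMANDA
MARGE,MARGARET
MATT,MATTHEW
MAX,MAXWELL
MEG,MARGARET
MEL,MELISSA
MICK,MICHAEL
MIKE,MICHAEL
MIKEY,MICHAEL
MOLLY,MARY
NATE,NATHAN
NED,EDWARD
NICK,NICHOLAS
NICKY,NICHOLAS
PAT,PATRICK
PATSY,PATRICIA
PATTY,PATRICIA
PEG,MARGARET
PEGGY,MARGARET
PETE,PETER
PHIL,PHILIP
RAY,RAYMOND
RICH,RICHARD
RICK,RICHARD
RICKY,RICHARD
ROB,ROBERT
ROBBIE,ROBERT
RON,RONALD
RONNIE,RONALD
ROSIE,ROSEMARY
RUSS,RUSSELL
SAL,SALVATORE
SALLY,SARAH
SAM,SAMUEL
SAMMY,SAMUEL
SANDY,SANDRA
SID,SIDNEY
STAN,STANLEY
STEVE,STEPHEN
STEVIE,STEPHEN
SUE,SUSAN
SUSIE,SUSAN
TED,EDWARD
TEDDY,EDWARD
TERRY,TERENCE
TESS,THERESA
TIM,TIMOTHY
TIMMY,TIMOTHY
TINA,CHRISTINA
TOBY,TOBIAS
TOM,THOMAS
TOMMY,THOMAS
TONY,ANTHONY
TRISH,PATRICIA
VAL,VALERIE
VICKY,VICTORIA
VINCE,VINCENT
WALT,WALTER
WILL,WILLIAM
WILLY,WILLIAM
ZACH,ZACHARY
ZAK,ZACHARY
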